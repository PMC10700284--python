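# Session JSON format

One session = one UTF-8 JSON document, self-contained: everything needed
to process the session (metadata, events, pauses, and the keystroke
schema in force) is embedded. Field order is fixed as listed so diffs
stay stable.

```jsonc
{
  "format_version": 1,
  "info": {
    "mrn": "000000",                  // medical record number
    "assessment": "Functional Analysis",
    "condition": "baseline",          // must be in schema.conditions when non-empty
    "therapist": "Therapist A",
    "data_recorder": "Recorder B",
    "concern": "Self-injury",         // referral concern
    "phase": "Assessment",            // "Assessment" | "Treatment"
    "session_number": "1",            // free text; integers join the duplicate check
    "is_reliability": false,
    "start_datetime": "2023-03-05T09:00:00",  // ISO-8601
    "duration": 120.0,                // session seconds (pauses excluded)
    "video_fps": null                 // positive real when a video is attached
  },
  "freq_events": [                    // sorted by t
    {"tag": "hitting", "t": 3.25, "frame": 97}   // frame optional
  ],
  "dur_events": [                     // sorted by start; 0 <= start <= end <= duration
    {"tag": "aggression", "start": 2.0, "end": 7.5,
     "start_frame": null, "end_frame": null}
  ],
  "pauses": [                         // wall-clock seconds, disjoint, ordered
    {"wall_start": 160.0, "wall_end": 175.0}
  ],
  "schema": {                         // full snapshot of the keystroke schema
    "name": "demo",
    "revision": 0,
    "bindings": [
      {"key": "a", "behavior": "hitting", "kind": "frequency"},
      {"key": "z", "behavior": "aggression", "kind": "duration"}
    ],
    "conditions": ["baseline", "treatment"]
  },
  "physio_ref": null                  // optional path to a wearable recording
}
```

Validation on load re-checks every invariant: events sorted, every tag
resolvable in the embedded schema with the right binding kind, no event
past `duration`, pauses disjoint and ordered, `condition` drawn from the
schema's conditions when any are declared. Missing required fields are
reported by name.
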