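{
  "title": "perisim clinical report",
  "required": {
    "name": "string",
    "dob": "string",
    "gender": "string",
    "test_id": "string",
    "exam_date": "string",
    "test_time": "string",
    "strategy": "string",
    "normative": "string",
    "per_eye": "object"
  },
  "per_eye_required": [
    "fixation_losses",
    "false_positives",
    "false_negatives",
    "thresholds",
    "grayscale",
    "md",
    "psd"
  ]
}
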