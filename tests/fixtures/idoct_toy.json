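{
 "trials": [
  {
   "participant_id": "A",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 0,
   "condition_label": "c01",
   "accuracy": 1,
   "rt": 400.0,
   "timed_out": 0
  },
  {
   "participant_id": "A",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 1,
   "condition_label": "c01",
   "accuracy": 1,
   "rt": 500.0,
   "timed_out": 0
  },
  {
   "participant_id": "A",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 2,
   "condition_label": "c02",
   "accuracy": 1,
   "rt": 800.0,
   "timed_out": 0
  },
  {
   "participant_id": "A",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 3,
   "condition_label": "c02",
   "accuracy": 0,
   "rt": 900.0,
   "timed_out": 0
  },
  {
   "participant_id": "B",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 4,
   "condition_label": "c01",
   "accuracy": 1,
   "rt": 600.0,
   "timed_out": 0
  },
  {
   "participant_id": "B",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 5,
   "condition_label": "c01",
   "accuracy": 0,
   "rt": 700.0,
   "timed_out": 0
  },
  {
   "participant_id": "B",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 6,
   "condition_label": "c02",
   "accuracy": 1,
   "rt": 1000.0,
   "timed_out": 0
  },
  {
   "participant_id": "B",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 7,
   "condition_label": "c02",
   "accuracy": 0,
   "rt": 1100.0,
   "timed_out": 0
  },
  {
   "participant_id": "C",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 8,
   "condition_label": "c01",
   "accuracy": 1,
   "rt": 500.0,
   "timed_out": 0
  },
  {
   "participant_id": "C",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 9,
   "condition_label": "c01",
   "accuracy": 1,
   "rt": 600.0,
   "timed_out": 0
  },
  {
   "participant_id": "C",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 10,
   "condition_label": "c02",
   "accuracy": 1,
   "rt": 900.0,
   "timed_out": 0
  },
  {
   "participant_id": "C",
   "task_id": "toy",
   "session_index": 0,
   "trial_index": 11,
   "condition_label": "c02",
   "accuracy": 1,
   "rt": 1000.0,
   "timed_out": 0
  }
 ],
 "w": 0.5,
 "expected": {
  "rt_floor": 455.0,
  "rt_ceiling": 1045.0,
  "speed_scores": [
   1.0,
   0.923728813559322,
   0.4152542372881356,
   0.2457627118644068,
   0.7542372881355932,
   0.5847457627118644,
   0.07627118644067797,
   0.0,
   0.923728813559322,
   0.7542372881355932,
   0.2457627118644068,
   0.07627118644067797
  ],
  "trial_performance": [
   1.0,
   0.961864406779661,
   0.7076271186440678,
   0.0,
   0.8771186440677966,
   0.0,
   0.538135593220339,
   0.0,
   0.961864406779661,
   0.8771186440677966,
   0.6228813559322034,
   0.538135593220339
  ],
  "d_raw": {
   "c01": 0.22033898305084743,
   "c02": 0.5988700564971752
  },
  "d_scaled": {
   "c01": 0.22033898305084743,
   "c02": 0.5988700564971752
  },
  "at_curve": {
   "c01": 452.0,
   "c02": 852.0
  },
  "dt": {
   "A": 0.0,
   "B": 198.0,
   "C": 98.0
  },
  "dt_reference_mean": 98.66666666666667,
  "decomposition": {
   "A": {
    "delay_time": 0.0,
    "cognitive_index": 0.47570231833235926,
    "answer_times": [
     400.0,
     500.0,
     800.0,
     900.0
    ]
   },
   "B": {
    "delay_time": 198.0,
    "cognitive_index": 0.3567455678940191,
    "answer_times": [
     402.0,
     502.0,
     802.0,
     902.0
    ]
   },
   "C": {
    "delay_time": 98.0,
    "cognitive_index": 0.671118254432106,
    "answer_times": [
     402.0,
     502.0,
     802.0,
     902.0
    ]
   }
  }
 }
}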