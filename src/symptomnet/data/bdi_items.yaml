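# 21-item depression inventory: item labels and three-factor symptom
# categories (negative attitude / performance difficulty / somatic elements).
items:
  - {id: 1, label: "Sadness", category: negative_attitude}
  - {id: 2, label: "Pessimism", category: negative_attitude}
  - {id: 3, label: "Past Failure", category: negative_attitude}
  - {id: 4, label: "Loss of Pleasure", category: performance_difficulty}
  - {id: 5, label: "Guilty Feelings", category: negative_attitude}
  - {id: 6, label: "Punishment Feelings", category: negative_attitude}
  - {id: 7, label: "Self-Dislike", category: negative_attitude}
  - {id: 8, label: "Self-Criticalness", category: negative_attitude}
  - {id: 9, label: "Suicidal Thoughts or Wishes", category: negative_attitude}
  - {id: 10, label: "Crying", category: negative_attitude}
  - {id: 11, label: "Agitation", category: performance_difficulty}
  - {id: 12, label: "Loss of Interest", category: performance_difficulty}
  - {id: 13, label: "Indecisiveness", category: performance_difficulty}
  - {id: 14, label: "Worthlessness", category: negative_attitude}
  - {id: 15, label: "Loss of Energy", category: performance_difficulty}
  - {id: 16, label: "Changes in Sleeping Pattern", category: somatic_elements}
  - {id: 17, label: "Irritability", category: performance_difficulty}
  - {id: 18, label: "Changes in Appetite", category: somatic_elements}
  - {id: 19, label: "Concentration Difficulty", category: performance_difficulty}
  - {id: 20, label: "Tiredness or Fatigue", category: performance_difficulty}
  - {id: 21, label: "Loss of Interest in Sex", category: somatic_elements}
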