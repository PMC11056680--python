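# Canonical eight-arm configuration: one row per study arm across the five
# workflow decision axes (source, dedup stages, classifier gate, priority
# screening, fixed weekly target, target recall).
arms:
  - {arm_id: 1, label: "Comparator A",   source: ME,  dedup_between_sources: true,  dedup_against_known: true, classifier_gate: false, priority_screening: false, fixed_target_per_week: null, target_recall: 1.0}
  - {arm_id: 2, label: "Comparator B",   source: ME,  dedup_between_sources: true,  dedup_against_known: true, classifier_gate: false, priority_screening: false, fixed_target_per_week: null, target_recall: 0.95}
  - {arm_id: 3, label: "Comparator C",   source: ME,  dedup_between_sources: true,  dedup_against_known: true, classifier_gate: false, priority_screening: false, fixed_target_per_week: 1500, target_recall: 0.95}
  - {arm_id: 4, label: "Intervention A", source: ME,  dedup_between_sources: true,  dedup_against_known: true, classifier_gate: true,  priority_screening: false, fixed_target_per_week: null, target_recall: 0.95}
  - {arm_id: 5, label: "Intervention B", source: ME,  dedup_between_sources: true,  dedup_against_known: true, classifier_gate: true,  priority_screening: true,  fixed_target_per_week: 1500, target_recall: 0.95}
  - {arm_id: 6, label: "Intervention C", source: MAG, dedup_between_sources: false, dedup_against_known: true, classifier_gate: false, priority_screening: false, fixed_target_per_week: null, target_recall: 1.0}
  - {arm_id: 7, label: "Intervention D", source: MAG, dedup_between_sources: false, dedup_against_known: true, classifier_gate: true,  priority_screening: false, fixed_target_per_week: null, target_recall: 0.95}
  - {arm_id: 8, label: "Intervention E", source: MAG, dedup_between_sources: false, dedup_against_known: true, classifier_gate: true,  priority_screening: true,  fixed_target_per_week: 1500, target_recall: 0.95}
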