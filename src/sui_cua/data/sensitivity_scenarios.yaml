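# Deterministic sensitivity scenarios applied identically to both arms.
# Components refer to CostBreakdown fields; "laundry cost" is the goods cost
# of extra laundry loads, distinct from the participant's laundry time.
scenarios:
  - name: pfmt_time_halved
    modifications:
      - {component: pfmt_time, action: scale, factor: 0.5}
  - name: laundry_cost_halved
    modifications:
      - {component: laundry_loads, action: scale, factor: 0.5}
  - name: laundry_time_excluded
    modifications:
      - {component: laundry_time, action: exclude}
  - name: multiway
    modifications:
      - {component: pfmt_time, action: scale, factor: 0.5}
      - {component: laundry_loads, action: scale, factor: 0.5}
      - {component: laundry_time, action: exclude}
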