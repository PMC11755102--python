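{
  "comment": "Published national reference values, Romania 2022, used by the `ad-coi reproduce` diff. Severity triples are [mild, moderate, severe]. Monetary values in EUR as printed (1 decimal where available).",
  "cases": {
    "adult": {"prevalence": [11969, 31239, 9593], "incidence": [1930, 5038, 1547]},
    "pediatric": {"prevalence": [39671, 37867, 25245], "incidence": [5066, 4836, 3224]}
  },
  "hospitalizations": {
    "adult": {"prevalence": [93, 243, 75], "incidence": [108, 281, 86]},
    "pediatric": {"prevalence": [308, 294, 196], "incidence": [283, 270, 180]}
  },
  "workers_full_time": {
    "adult": {"prevalence": [2163, 17125, 2600], "incidence": [349, 2762, 419]},
    "pediatric": {"prevalence": [13224, 16830, 5610], "incidence": [1689, 2149, 716]}
  },
  "workers_part_time": {
    "adult": {"prevalence": [1496, 21477, 1799], "incidence": [241, 3464, 290]},
    "pediatric": {"prevalence": [0, 37867, 0], "incidence": [0, 4836, 0]}
  },
  "grand_totals": {
    "adult": {
      "prevalence": 29810077.2,
      "incidence": 5529867.8,
      "prevalence_prescription": 22380128.1,
      "incidence_prescription": 4331672.1
    },
    "pediatric": {
      "prevalence": 133635535.2,
      "incidence": 53175049.1,
      "prevalence_prescription": 120746634.9,
      "incidence_prescription": 51529194.2
    }
  },
  "average_overall": {
    "adult": {
      "prevalence": 564.6,
      "incidence": 649.4,
      "prevalence_prescription": 423.9,
      "incidence_prescription": 508.7
    },
    "pediatric": {
      "prevalence": 1300.2,
      "incidence": 4051.4,
      "prevalence_prescription": 1174.8,
      "incidence_prescription": 3926.03
    }
  },
  "average_per_severity": {
    "adult": {
      "prevalence": [284.7, 550.3, 960.1],
      "incidence": [369.6, 635.2, 1045.0],
      "prevalence_prescription": [176.6, 433.2, 701.8],
      "incidence_prescription": [261.4, 518.1, 786.7]
    },
    "pediatric": {
      "prevalence": [374.9, 2614.8, 782.2],
      "incidence": [758.12, 9558.5, 967.4],
      "prevalence_prescription": [293.72, 2491.7, 584.0],
      "incidence_prescription": [676.9, 9435.4, 769.2]
    }
  },
  "component_cells": {
    "adult": {
      "prevalence": {
        "treatment": [1392698.1, 3913664.59, 2556162.1],
        "treatment_prescription": [98057.0, 255927.6, 78591.3],
        "medical_services": [732513.6, 4946243.6, 3567733.1],
        "associated": [852900.2, 3051492.8, 2102900.4],
        "hospitalization": [164041.3, 428136.2, 131465.7],
        "productivity_ft": [107056.4, 918088.9, 406923.0],
        "productivity_pt": [158673.0, 3934310.0, 445073.0]
      },
      "incidence": {
        "treatment": [224572.5, 631167.5, 412215.4],
        "treatment_prescription": [15811.7, 41274.1, 12673.9],
        "medical_services": [118117.7, 797694.4, 575344.8],
        "associated": [137530.6, 492122.7, 339120.9],
        "hospitalization": [190211.3, 496438.1, 152438.9],
        "productivity_ft": [17267.0, 148073.8, 65632.5],
        "productivity_pt": [25592.4, 634543.4, 71784.3]
      }
    },
    "pediatric": {
      "prevalence": {
        "treatment": [3547085.3, 4973006.9, 5210755.8],
        "treatment_prescription": [325007.3, 310227.9, 206821.3],
        "associated": [4314982.7, 6691554.2, 10787181.0],
        "hospitalization": [280887.6, 268120.0, 178746.64],
        "productivity_ft": [6731690.9, 11780459.0, 3569836.1],
        "productivity_pt": [0.0, 75301229.4, 0.0]
      },
      "incidence": {
        "treatment": [452952.6, 634972.1, 665457.6],
        "treatment_prescription": [41503.54, 39611.1, 26412.83],
        "associated": [551010.84, 854402.6, 1377614.2],
        "hospitalization": [257868.4, 246147.0, 164098.1],
        "productivity_ft": [2578839.7, 6017216.2, 911741.8],
        "productivity_pt": [0.0, 38462727.7, 0.0]
      }
    }
  },
  "segment_component_totals": {
    "adult": {
      "prevalence": {
        "treatment": 7862524.77,
        "medical_services": 9246490.26,
        "hospitalization": 723643.3,
        "associated": 6007293.39,
        "productivity_ft": 1432069.3,
        "productivity_pt": 4538056.2,
        "treatment_prescription": 432575.7
      },
      "incidence": {
        "treatment": 1267955.4,
        "medical_services": 1491157.0,
        "hospitalization": 839088.28,
        "associated": 968773.7,
        "productivity_ft": 230973.4,
        "productivity_pt": 731920.1,
        "treatment_prescription": 69759.7
      }
    },
    "pediatric": {
      "prevalence": {
        "treatment": 13730848.0,
        "hospitalization": 727754.2,
        "associated": 21793718.0,
        "productivity_ft": 22081985.9,
        "productivity_pt": 75301229.4,
        "treatment_prescription": 842056.5
      },
      "incidence": {
        "treatment": 1753842.2,
        "hospitalization": 668113.6,
        "associated": 2783027.0,
        "productivity_ft": 9507797.7,
        "productivity_pt": 38462727.7,
        "treatment_prescription": 107527.4
      }
    }
  }
}
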