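"""Published per-condition reference values, shipped as worked-example fixtures.

These are the printed results of the source clinical/computational study of
a 6-year-old with Alagille's syndrome (volumetrics from cine MRI, workload /
MVO2 / coronary indices from the patient-specific simulation).  They are
used (a) as calibration anchors (Rest MVO2), and (b) as fixtures for the
table-arithmetic worked examples (EF, CFR, percent changes).  Simulated
coronary values of this package are never asserted against Table 3.
"""

from __future__ import annotations

#: Volumetric parameters per condition.  Volumes indexed in mL/m², EF %.
TABLE1 = {
    "Rest": {"hr": 73, "mass_index_lv": 54.2, "mass_index_rv": 59.8,
             "edv_lv": 81, "edv_rv": 90, "esv_lv": 35, "esv_rv": 44,
             "ef_lv": 60, "ef_rv": 51},
    "Stress": {"hr": 106, "mass_index_lv": 54.2, "mass_index_rv": 59.8,
               "edv_lv": 80, "edv_rv": 95, "esv_lv": 23, "esv_rv": 37,
               "ef_lv": 71, "ef_rv": 61},
}

#: Cardiac workload (J) and MVO2 (mL/min) per condition and ventricle.
TABLE2 = {
    "Rest": {"workload_lv": 4.6e-1, "workload_rv": 3.5e-1,
             "mvo2_lv": 5.42, "mvo2_rv": 5.10},
    "Stress": {"workload_lv": 5.2e-1, "workload_rv": 7.2e-1,
               "mvo2_lv": 6.97, "mvo2_rv": 7.93},
    "PRS": {"workload_lv": 2.7e-1, "workload_rv": 4.9e-1,
            "mvo2_lv": 4.39, "mvo2_rv": 8.91},
}

#: Coronary blood flow (reported per gram), diastolic:systolic integrated
#: flow pairs, and coronary resistance (WU·m²) per condition and territory.
TABLE3 = {
    "Rest": {"cbf_lca": 66.2, "cbf_rca": 67.6,
             "ds_pair_lca": (36.8, 29.4), "ds_pair_rca": (35.6, 32.0),
             "r_lca": 1.07e2, "r_rca": 1.05e2},
    "Stress": {"cbf_lca": 88.3, "cbf_rca": 93.4,
               "ds_pair_lca": (53.0, 35.3), "ds_pair_rca": (58.8, 34.6),
               "r_lca": 6.50e1, "r_rca": 5.83e1},
    "PRS": {"cbf_lca": 51.5, "cbf_rca": 44.6,
            "ds_pair_lca": (15.4, 36.1), "ds_pair_rca": (23.4, 21.2),
            "r_lca": 2.36e1, "r_rca": 1.42e1},
}

#: Fixed oxygen extraction fractions per territory and condition.
EXTRACTION = {
    "Rest": {"LCA": 0.8, "RCA": 0.4},
    "Stress": {"LCA": 1.0, "RCA": 1.0},
    "PRS": {"LCA": 1.0, "RCA": 1.0},
}

#: Rest MVO2 anchors (mL/min) used to fit the PVA→MVO2 constants.
REST_MVO2_ANCHORS = {"LV": TABLE2["Rest"]["mvo2_lv"], "RV": TABLE2["Rest"]["mvo2_rv"]}

#: MAP drop defining the post-reperfusion-syndrome condition.
PRS_MAP_DROP = 0.31

#: Reported flow-based cardiac-output rise at peak dobutamine stress.
STRESS_CO_RATIO = 1.45
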