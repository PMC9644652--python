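"""Reference validation-cohort aggregates.

Published per-subject aggregates from a clinical validation cohort: 24
epilepsy patients (14 of whom underwent the Wada test: 8 with left and 6
with atypical language dominance) and 9 healthy controls, each assessed
with the MEG beta-desynchronization pipeline and with fMRI. For every
subject and each of the three language ROI pairs (IFG: pars opercularis +
triangularis; WA: angular, supramarginal and superior temporal; TIMP:
middle/inferior temporal and temporal poles) the tables list the left and
right sums of threshold-surviving t-values together with the laterality
index as printed in the reference tables (2 decimals).

These aggregates serve as worked examples and as the fixed inputs for the
agreement statistics between MEG, fMRI and Wada categories; a right-side
sum of 0.0 means no suprathreshold voxel survived on that side (forcing
LI = +-1).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .laterality import DICH_ATYPICAL, DICH_LEFT

ROIS = ("IFG", "WA", "TIMP")

#: Wada-test outcome per patient id. ``R/L*`` marks right dominance with
#: partial left comprehension, ``Bil/R`` bilateral dominance with right
#: emphasis; both count as atypical (non-left) when dichotomized.
WADA_RAW = {
    1: "R", 2: "L", 3: "L", 4: "L", 6: "R/L*", 8: "Bil/R",
    10: "R", 12: "L", 13: "L", 14: "R", 17: "L", 20: "L", 21: "R", 23: "L",
}

_MEG_CONTROLS = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li,corrected
1,3357.0,0.0,1.0,3478.9,0.0,1.0,5745.9,0.0,1.0,True
2,7818.0,0.0,1.0,5025.8,0.0,1.0,10838.1,0.0,1.0,True
3,5352.4,0.0,1.0,6629.9,0.0,1.0,11682.3,0.0,1.0,True
4,7043.9,0.0,1.0,2961.0,0.0,1.0,5866.4,0.0,1.0,True
5,427.8,0.0,1.0,647.7,0.0,1.0,43.5,0.0,1.0,False
6,224.1,0.0,1.0,1833.9,0.0,1.0,3784.2,0.0,1.0,True
7,4132.2,0.0,1.0,4938.0,0.0,1.0,7441.1,0.0,1.0,True
8,6427.7,0.0,1.0,3034.3,0.0,1.0,4945.0,0.0,1.0,True
9,2821.7,0.0,1.0,2223.6,0.0,1.0,4241.7,0.0,1.0,True
"""

_MEG_LEFT_WADA = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li
2,4767.6,2660.2,0.28,3495.9,1332.2,0.45,4331.1,1921.4,0.39
3,2266.8,0.0,1.00,898.5,0.0,1.00,2574.1,0.0,1.00
4,1683.5,0.0,1.00,1059.6,0.0,1.00,984.7,0.0,1.00
12,4122.3,0.0,1.00,3705.3,0.0,1.00,5830.0,0.0,1.00
13,3133.3,0.0,1.00,2232.2,736.0,0.50,4487.4,1580.3,0.48
17,10022.9,0.0,1.00,8469.7,1341.7,0.73,14023.9,1487.8,0.81
20,9408.3,0.0,1.00,5911.1,1149.1,0.67,8661.9,1482.7,0.71
23,4466.0,0.0,1.00,1134.8,0.0,1.00,5075.7,0.0,1.00
"""

_MEG_ATYPICAL_WADA = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li
1,3433.5,5345.1,-0.22,408.0,4857.7,-0.85,951.2,8036.6,-0.79
6,520.6,2789.0,-0.69,2803.4,3557.7,-0.12,4064.1,3879.9,0.02
8,0.0,5242.5,-1.00,0.0,2834.5,-1.00,0.0,3550.3,-1.00
10,0.0,1567.4,-1.00,0.0,35.5,-1.00,0.0,1267.2,-1.00
14,0.0,5063.4,-1.00,0.0,1778.8,-1.00,0.0,4326.2,-1.00
21,3956.3,6696.0,-0.26,489.4,1933.9,-0.60,3313.5,6539.9,-0.33
"""

_FMRI_CONTROLS = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li
1,2278.3,125.4,0.90,606.6,133.1,0.64,1804.5,137.7,0.86
2,1345.0,388.9,0.55,442.2,391.1,0.06,941.7,63.7,0.87
3,2819.3,101.6,0.93,492.0,92.0,0.68,1610.2,122.1,0.86
4,1148.1,0.0,1.00,456.4,96.9,0.65,1082.6,45.1,0.92
5,539.8,120.6,0.63,268.8,315.8,-0.08,135.6,43.4,0.52
6,1135.0,37.5,0.94,286.7,109.3,0.45,851.4,57.2,0.87
7,1205.9,7.1,0.99,181.5,162.4,0.06,728.5,257.9,0.48
8,2136.6,82.2,0.93,1116.0,149.9,0.76,2526.5,190.4,0.86
9,1799.2,64.1,0.93,11.6,78.9,-0.74,712.3,68.7,0.82
"""

_FMRI_LEFT_WADA = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li
2,1887.6,247.0,0.77,205.5,1163.7,-0.70,754.1,1464.3,-0.32
3,787.5,22.1,0.95,79.6,29.7,0.46,246.6,21.7,0.84
4,1814.9,122.9,0.87,189.3,352.8,-0.30,643.8,610.5,0.03
12,1131.4,72.9,0.88,474.1,160.6,0.49,754.4,234.8,0.53
13,1316.8,152.3,0.79,83.5,103.7,-0.11,355.6,390.7,-0.05
17,1851.4,44.1,0.95,51.2,139.0,-0.46,313.1,46.9,0.74
20,2534.1,2000.2,0.12,887.7,1206.5,-0.15,1487.4,1283.9,0.07
23,3663.2,415.0,0.80,942.9,108.9,0.79,873.3,111.6,0.77
"""

_FMRI_ATYPICAL_WADA = """subject,IFG_left,IFG_right,IFG_li,WA_left,WA_right,WA_li,TIMP_left,TIMP_right,TIMP_li
1,2552.3,3843.3,-0.20,249.6,781.2,-0.52,537.5,815.9,-0.21
6,1213.4,926.0,0.13,19.3,714.4,-0.95,219.7,793.1,-0.57
8,441.5,1217.7,-0.47,127.6,738.9,-0.71,37.9,542.6,-0.87
10,1328.6,1585.6,-0.09,404.4,609.4,-0.20,807.2,548.7,0.19
14,180.7,0.0,1.00,0.0,95.2,-1.00,19.6,118.2,-0.72
21,1454.5,2388.4,-0.24,136.4,689.8,-0.67,436.7,830.3,-0.31
"""

_WIDE = {
    ("MEG", "control"): _MEG_CONTROLS,
    ("MEG", "left_wada"): _MEG_LEFT_WADA,
    ("MEG", "atypical_wada"): _MEG_ATYPICAL_WADA,
    ("fMRI", "control"): _FMRI_CONTROLS,
    ("fMRI", "left_wada"): _FMRI_LEFT_WADA,
    ("fMRI", "atypical_wada"): _FMRI_ATYPICAL_WADA,
}


def wada_trichotomous(raw: str) -> str:
    """Canonical L/R/Bil category from an annotated Wada outcome."""
    return {"L": "L", "R": "R", "R/L*": "R", "Bil/R": "Bil"}[raw]


def wada_dichotomous(raw: str) -> str:
    return DICH_LEFT if wada_trichotomous(raw) == "L" else DICH_ATYPICAL


def cohort_table(modality: str | None = None, group: str | None = None) -> pd.DataFrame:
    """Tidy per-subject/ROI aggregates.

    Columns: modality, group, subject, wada (raw annotation, empty for
    controls), roi, left_sum, right_sum, li_printed, corrected.
    """
    rows = []
    for (mod, grp), csv_text in _WIDE.items():
        wide = pd.read_csv(StringIO(csv_text))
        for _, r in wide.iterrows():
            subject = int(r["subject"])
            corrected = bool(r["corrected"]) if "corrected" in wide.columns else True
            for roi in ROIS:
                rows.append({
                    "modality": mod,
                    "group": grp,
                    "subject": subject,
                    "wada": WADA_RAW.get(subject, "") if grp != "control" else "",
                    "roi": roi,
                    "left_sum": float(r[f"{roi}_left"]),
                    "right_sum": float(r[f"{roi}_right"]),
                    "li_printed": float(r[f"{roi}_li"]),
                    "corrected": corrected,
                })
    df = pd.DataFrame(rows)
    if modality is not None:
        df = df[df["modality"] == modality]
    if group is not None:
        df = df[df["group"] == group]
    return df.reset_index(drop=True)


def wada_patients(modality: str) -> pd.DataFrame:
    """The 14 Wada-tested patients of one modality, all ROIs."""
    df = cohort_table(modality=modality)
    return df[df["group"].isin(["left_wada", "atypical_wada"])].reset_index(drop=True)
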