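"""Brain parcellation bookkeeping.

The package ships a default 90-region cortical/subcortical parcellation
(the AAL atlas restricted to the cerebrum, 45 homologous regions per
hemisphere, interleaved left/right as in the atlas numbering).  Each
region carries a hemisphere label (``L``/``R``, parsed from the name
suffix) and one of six lobe groups — frontal, temporal, parietal,
medial temporal, occipital, subcortical — following the standard
anatomical grouping used for connectome reporting.

Region indices are 1-based in every file and report; 0-based only
inside numpy arrays.
"""

from __future__ import annotations

import io

import pandas as pd

LOBES = (
    "frontal",
    "temporal",
    "parietal",
    "medial temporal",
    "occipital",
    "subcortical",
)

# 45 homologous region stems in atlas order; each expands to _L then _R.
_AAL_STEMS: list[tuple[str, str]] = [
    ("Precentral", "frontal"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "frontal"),
    ("Supp_Motor_Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Insula", "subcortical"),
    ("Cingulum_Ant", "frontal"),
    ("Cingulum_Mid", "frontal"),
    ("Cingulum_Post", "parietal"),
    ("Hippocampus", "medial temporal"),
    ("ParaHippocampal", "medial temporal"),
    ("Amygdala", "medial temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Fusiform", "occipital"),
    ("Postcentral", "parietal"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral_Lobule", "frontal"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Thalamus", "subcortical"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
]


def default_region_table() -> pd.DataFrame:
    """Return the packaged 90-row region table.

    Columns: ``index`` (1-based), ``name``, ``hemisphere`` (L/R),
    ``lobe`` (one of :data:`LOBES`).
    """
    rows = []
    idx = 1
    for stem, lobe in _AAL_STEMS:
        for hemi in ("L", "R"):
            rows.append((idx, f"{stem}_{hemi}", hemi, lobe))
            idx += 1
    return pd.DataFrame(rows, columns=["index", "name", "hemisphere", "lobe"])


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a user-supplied region table and return it normalized.

    Requires unique 1..N indices, a hemisphere label in {L, R} and a
    lobe label for every region.
    """
    required = {"index", "name", "hemisphere", "lobe"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    table = table.copy()
    table["index"] = table["index"].astype(int)
    n = len(table)
    if sorted(table["index"]) != list(range(1, n + 1)):
        raise ValueError("region indices must be exactly 1..N and unique")
    bad_hemi = set(table["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate region names: {dupes}")
    return table.sort_values("index").reset_index(drop=True)


def read_region_table(path) -> pd.DataFrame:
    return validate_region_table(pd.read_csv(path))


def write_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def lobe_labels(table: pd.DataFrame) -> list[str]:
    """Lobe label per region, in index order."""
    return list(validate_region_table(table)["lobe"])


def region_names(table: pd.DataFrame) -> list[str]:
    return list(validate_region_table(table)["name"])
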