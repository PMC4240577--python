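"""Pairwise group comparisons and pattern-based marker classification.

Each protein is compared across the four study groups — patients at baseline
(T2DM0) and after the diet (T2DM16), obese controls and lean controls — with
a paired t-test for the within-subject pair and Welch t-tests otherwise,
BH-adjusted across proteins within each of the six comparison families.
The resulting significance pattern assigns a marker category: a within-diet
change makes a DIET marker; patients differing from both control groups
(which do not differ from each other) at both timepoints makes a DIABETES
marker; lean subjects differing from all obese groups (diabetic or not)
makes an OBESITY marker.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    BASELINE,
    LEAN_CTRL,
    OBESE_CTRL,
    PATIENT_GROUPS,
    StudyDesign,
)
from .stats import bh_adjust, independent_ttest, paired_ttest

GROUP_LABELS = ("T2DM0", "T2DM16", "OBESE", "LEAN")
COMPARISONS = (
    ("T2DM0", "T2DM16"),   # paired within-subject contrast
    ("T2DM0", "OBESE"),
    ("T2DM0", "LEAN"),
    ("T2DM16", "OBESE"),
    ("T2DM16", "LEAN"),
    ("OBESE", "LEAN"),
)

DIET = "DIET"
DIABETES = "DIABETES"
OBESITY = "OBESITY"
NON_ASSOCIATED = "NON_ASSOCIATED"
AMBIGUOUS = "AMBIGUOUS"


def _group_columns(design: StudyDesign) -> dict[str, list[str]]:
    cols: dict[str, list[str]] = {g: [] for g in GROUP_LABELS}
    for s in design.samples:
        if s.group in PATIENT_GROUPS:
            cols["T2DM0" if s.timepoint == BASELINE else "T2DM16"].append(s.sample_id)
        elif s.group == OBESE_CTRL:
            cols["OBESE"].append(s.sample_id)
        elif s.group == LEAN_CTRL:
            cols["LEAN"].append(s.sample_id)
    for label, ids in cols.items():
        if not ids:
            raise ValueError(f"study group {label} has no samples")
    return cols


def pairwise_comparisons(
    abundance: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """All six group comparisons for every protein.

    Returns a long table (protein, group_a, group_b, paired, t, p, p_bh,
    direction, zero_variance, n_a, n_b).  Zero-variance comparisons carry
    p = 1 and are flagged.  BH adjustment runs across proteins within each
    comparison family.
    """
    cols = _group_columns(design)
    # subject-matched ordering for the paired contrast
    subj_t0 = {design.sample(c).subject_id: c for c in cols["T2DM0"]}
    subj_t16 = {design.sample(c).subject_id: c for c in cols["T2DM16"]}
    paired_subjects = sorted(set(subj_t0) & set(subj_t16))

    rows = []
    for prot, vals in abundance.iterrows():
        for ga, gb in COMPARISONS:
            paired = (ga, gb) == ("T2DM0", "T2DM16")
            if paired:
                a = vals[[subj_t0[s] for s in paired_subjects]].to_numpy(dtype=float)
                b = vals[[subj_t16[s] for s in paired_subjects]].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                a, b = a[ok], b[ok]
                res = paired_ttest(a, b) if len(a) >= 2 else None
                # paired test is (followup - baseline): flip so t refers a vs b
                if res is not None:
                    res.t = -res.t
            else:
                a = vals[cols[ga]].to_numpy(dtype=float)
                b = vals[cols[gb]].to_numpy(dtype=float)
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                res = independent_ttest(a, b) if len(a) >= 2 and len(b) >= 2 else None
            if res is None:
                t, p, zv = np.nan, 1.0, True
            elif res.zero_variance:
                t, p, zv = res.t, 1.0, True
            else:
                t, p, zv = res.t, res.p, False
            rows.append((
                prot, ga, gb, paired, t, p, zv,
                "up" if np.nanmean(a) > np.nanmean(b) else "down",
                len(a), len(b),
            ))
    out = pd.DataFrame(rows, columns=[
        "protein", "group_a", "group_b", "paired", "t", "p", "zero_variance",
        "direction", "n_a", "n_b",
    ])
    out["p_bh"] = np.nan
    for (_, _), idx in out.groupby(["group_a", "group_b"]).groups.items():
        out.loc[idx, "p_bh"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def classify_markers(comparisons: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Assign one marker category per protein from the significance pattern.

    Rules on BH-adjusted p-values at ``alpha``, evaluated in order:
    DIET — the within-subject T2DM0 vs T2DM16 contrast is significant;
    DIABETES — both patient timepoints differ from both control groups while
    the controls do not differ from each other;
    OBESITY — lean controls differ from obese controls and from patients at
    baseline, while obese controls do not differ from baseline patients;
    NON_ASSOCIATED — nothing is significant; anything else is AMBIGUOUS.
    """
    labels = {}
    for prot, chunk in comparisons.groupby("protein", sort=True):
        sig = {}
        for _, r in chunk.iterrows():
            key = frozenset((r["group_a"], r["group_b"]))
            sig[key] = bool(r["p_bh"] < alpha)
        if len(sig) != 6:
            raise ValueError(f"protein {prot} lacks the six comparisons")

        def s(a: str, b: str) -> bool:
            return sig[frozenset((a, b))]

        if s("T2DM0", "T2DM16"):
            lab = DIET
        elif (s("T2DM0", "LEAN") and s("T2DM0", "OBESE")
              and s("T2DM16", "LEAN") and s("T2DM16", "OBESE")
              and not s("OBESE", "LEAN")):
            lab = DIABETES
        elif (s("OBESE", "LEAN") and s("T2DM0", "LEAN")
              and not s("T2DM0", "OBESE")):
            lab = OBESITY
        elif not any(sig.values()):
            lab = NON_ASSOCIATED
        else:
            lab = AMBIGUOUS
        labels[prot] = lab
    return pd.Series(labels, name="marker_category").sort_index()


def _edge_width(p: float, w_min: float = 0.5, w_max: float = 5.0) -> float:
    """Large p (indistinguishable groups) maps to a thick edge."""
    p = min(max(float(p), 1e-300), 1.0)
    return float(np.clip(w_max - (-np.log10(p)), w_min, w_max))


def comparison_graph_dot(comparisons_one: pd.DataFrame, name: str = "protein") -> str:
    """DOT document for one protein's four-group comparison graph."""
    if len(comparisons_one) != 6:
        raise ValueError("expected exactly six comparisons for one protein")
    lines = [f'graph "{name}" {{']
    for g in GROUP_LABELS:
        lines.append(f"  {g};")
    for _, r in comparisons_one.iterrows():
        w = _edge_width(r["p_bh"] if np.isfinite(r["p_bh"]) else 1.0)
        lines.append(
            f'  {r["group_a"]} -- {r["group_b"]} '
            f'[penwidth={w:.3f}, label="p={r["p_bh"]:.3g}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
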