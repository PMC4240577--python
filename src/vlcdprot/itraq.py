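"""iTRAQ reporter-ion quantification and reference-stability normalization.

Reporter intensities become peptide-level ratios against the two pooled-QC
channels (113/117), roll up to protein groups by the median, are normalized
by a reference-stability (geNorm-style) procedure, and pass a complete-case
filter before modelling.  All abundances are dimensionless ratios on the
reference-pool scale (~1 for a sample matching the pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PRIMARY_CHANNELS, QC_CHANNELS, PlexLayout, StudyDesign
from .inference import ProteinGroupSet

log = logging.getLogger(__name__)


@dataclass
class QuantResult:
    """Protein(group) x sample relative abundances with per-value peptide counts."""

    abundance: pd.DataFrame    # index: group_id, columns: sample_id, values: ratio
    n_peptides: pd.DataFrame   # same shape; peptides behind each value


def compute_peptide_ratios(
    reporters: pd.DataFrame,
    layouts: list[PlexLayout],
    qc_mode: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Per-(plex, peptide, sample) ratios to the pooled-reference channels.

    For each spectrum row and primary channel c the ratio is the average of
    the ratios to the two QC reporters, (I_c/I_113 + I_c/I_117)/2
    (``qc_mode="ratio_to_mean"`` divides by the mean QC intensity instead).
    Spectra of the same peptide within a plex collapse to the median ratio.
    Rows with a missing or non-positive QC channel are dropped and counted.
    """
    if qc_mode not in ("mean_of_ratios", "ratio_to_mean"):
        raise ValueError(f"unknown qc_mode {qc_mode!r}")
    lay_by_id = {lay.plex_id: lay for lay in layouts}
    unknown = set(reporters["plex_id"]) - set(lay_by_id)
    if unknown:
        raise ValueError(f"reporter rows reference unknown plexes: {sorted(unknown)}")

    qc_cols = [str(c) for c in QC_CHANNELS]
    vals = reporters.copy()
    num = vals[qc_cols + [str(c) for c in PRIMARY_CHANNELS]].to_numpy(dtype=float)
    num[num <= 0] = np.nan  # non-positive intensities carry no ratio information
    vals[qc_cols + [str(c) for c in PRIMARY_CHANNELS]] = num

    usable = vals[qc_cols].notna().all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("dropped %d spectra with missing/zero QC channels", n_dropped)
    vals = vals.loc[usable]

    out_rows = []
    for plex_id, chunk in vals.groupby("plex_id", sort=True):
        lay = lay_by_id[plex_id]
        if chunk.empty:
            continue
        i113 = chunk[qc_cols[0]].to_numpy()
        i117 = chunk[qc_cols[1]].to_numpy()
        for chan, sample_id in sorted(lay.primary_samples.items()):
            ic = chunk[str(chan)].to_numpy()
            if qc_mode == "mean_of_ratios":
                ratio = 0.5 * (ic / i113 + ic / i117)
            else:
                ratio = ic / (0.5 * (i113 + i117))
            sub = pd.DataFrame({
                "plex_id": plex_id,
                "peptide_id": chunk["peptide_id"].to_numpy(),
                "sample_id": sample_id,
                "ratio": ratio,
            }).dropna(subset=["ratio"])
            out_rows.append(sub)
    if not out_rows:
        raise RuntimeError("no usable spectra: every row lacked QC channel signal")
    long = pd.concat(out_rows, ignore_index=True)
    agg = (
        long.groupby(["plex_id", "peptide_id", "sample_id"], sort=True)["ratio"]
        .agg(ratio="median", n_spectra="size")
        .reset_index()
    )
    agg.attrs["n_dropped_spectra"] = n_dropped
    return agg


def rollup_protein_ratios(
    peptide_ratios: pd.DataFrame, groups: ProteinGroupSet
) -> QuantResult:
    """Protein-group ratios: median over the group's peptide ratios per sample."""
    pep_group = []
    for g in groups.groups:
        for pep in g.peptides:
            pep_group.append((pep, g.group_id))
    pg = pd.DataFrame(pep_group, columns=["peptide_id", "group_id"])
    merged = peptide_ratios.merge(pg, on="peptide_id", how="inner")
    missing = set(peptide_ratios["peptide_id"]) - set(pg["peptide_id"])
    if missing:
        raise ValueError(f"peptides without a protein group: {sorted(missing)[:5]} ...")
    agg = (
        merged.groupby(["group_id", "sample_id"], sort=True)["ratio"]
        .agg(ratio="median", n_peptides="size")
        .reset_index()
    )
    abundance = agg.pivot(index="group_id", columns="sample_id", values="ratio")
    npep = (
        agg.pivot(index="group_id", columns="sample_id", values="n_peptides")
        .fillna(0)
        .astype(int)
    )
    return QuantResult(abundance, npep)


@dataclass
class GenormState:
    """Reference-stability bookkeeping: M values, ranking, chosen references."""

    m_values: pd.Series                       # stability M_j per complete protein
    pairwise_v: pd.DataFrame                  # V_jk = SD over samples of log2 ratios
    ranked: list[str] = field(default_factory=list)       # ascending M
    inclusion_v: dict[int, float] = field(default_factory=dict)  # V(n, n+1)
    reference_set: list[str] = field(default_factory=list)
    norm_factors: pd.Series | None = None     # NF_i per sample


def genorm_stability(abundance: pd.DataFrame) -> GenormState:
    """Stability measure per protein on the complete-case submatrix.

    V_jk is the SD over samples of log2(a_ij / a_ik); M_j is the mean of V_jk
    over k != j.  Proteins with any missing value are excluded from the
    stability computation (but still get normalized later).
    """
    complete = abundance.dropna(axis=0)
    if (complete <= 0).any().any():
        raise ValueError("abundance ratios must be positive")
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 complete-case proteins for stability ranking, "
            f"have {len(complete)}"
        )
    logm = np.log2(complete.to_numpy(dtype=float))
    # SD over samples of (log a_j - log a_k) for all protein pairs
    p = logm.shape[0]
    diffs_sd = np.empty((p, p))
    for j in range(p):
        d = logm[j][None, :] - logm
        diffs_sd[j] = d.std(axis=1, ddof=1)
    np.fill_diagonal(diffs_sd, np.nan)
    v = pd.DataFrame(diffs_sd, index=complete.index, columns=complete.index)
    m = v.mean(axis=1, skipna=True)
    ranked = list(m.sort_values(kind="mergesort").index)  # stable: ties by index order
    return GenormState(m_values=m, pairwise_v=v, ranked=ranked)


def genorm_normalize(
    abundance: pd.DataFrame,
    state: GenormState,
    v_threshold: float = 0.15,
    floor: int = 3,
    cap: int = 10,
    scale: str = "invariant",
) -> tuple[pd.DataFrame, GenormState]:
    """Normalize samples by the geometric mean of the most stable proteins.

    Proteins are ranked by ascending M; the reference set is the smallest
    n in [floor, cap] whose inclusion-step variation V(n, n+1) — the SD over
    samples of log2(NF_n,i / NF_{n+1,i}) — falls below ``v_threshold``
    (n = cap if none does).

    ``scale="invariant"`` (default) divides each sample by its normalization
    factor, a'_ij = a_ij / NF_i, which is exactly invariant to any sample-wide
    multiplicative perturbation.  ``scale="preserve"`` additionally multiplies
    by the geometric mean of the NF_i so the output sits on the input's scale
    (a'_ij = a_ij * gmean(NF) / NF_i); that variant is not exactly invariant —
    a single-sample factor c leaks c^(1/S) into the global scale.
    """
    if floor < 2:
        raise ValueError("reference floor must be >= 2")
    if scale not in ("invariant", "preserve"):
        raise ValueError(f"unknown scale mode {scale!r}")
    ranked = state.ranked
    complete = abundance.loc[ranked]
    logm = np.log2(complete.to_numpy(dtype=float))

    def log_nf(n: int) -> np.ndarray:
        return logm[:n].mean(axis=0)

    cap_eff = min(cap, len(ranked))
    floor_eff = min(floor, cap_eff)
    inclusion: dict[int, float] = {}
    n_ref = cap_eff
    for n in range(floor_eff, cap_eff):
        vn = float(np.std(log_nf(n) - log_nf(n + 1), ddof=1))
        inclusion[n] = vn
        if vn < v_threshold:
            n_ref = n
            break
    state.inclusion_v = inclusion
    state.reference_set = ranked[:n_ref]
    log_nf_sel = log_nf(n_ref)
    nf = pd.Series(2.0 ** log_nf_sel, index=abundance.columns)
    state.norm_factors = nf
    gmean_nf = float(2.0 ** np.mean(log_nf_sel)) if scale == "preserve" else 1.0
    normalized = abundance.mul(gmean_nf / nf, axis=1)
    return normalized, state


@dataclass
class FilterCounts:
    n_total: int
    n_complete: int
    n_analyzed: int


def complete_case_filter(
    abundance: pd.DataFrame,
    design: StudyDesign,
    internal_controls: list[str] | None = None,
) -> tuple[pd.DataFrame, FilterCounts]:
    """Keep proteins measured for every patient sample at both timepoints,
    then drop flagged internal-control proteins."""
    internal_controls = internal_controls or []
    patient_cols = [s.sample_id for s in design.patient_samples]
    missing_cols = [c for c in patient_cols if c not in abundance.columns]
    n_total = len(abundance)
    if missing_cols:
        # samples never quantified at all: no protein is complete
        complete = abundance.iloc[0:0]
    else:
        complete = abundance[abundance[patient_cols].notna().all(axis=1)]
    analyzed = complete.drop(index=[c for c in internal_controls if c in complete.index])
    return analyzed, FilterCounts(n_total, len(complete), len(analyzed))
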