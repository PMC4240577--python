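"""Targeted MRM quantification against interleaved QC reference injections.

Fragment-ion signals from primary injections are normalized to the median
signal of the same fragment across a batch's QC injections, then rolled up
hierarchically (fragment -> peptide -> protein) with equal weight per peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import QC, MrmBatchLayout
from .itraq import QuantResult

log = logging.getLogger(__name__)

#: The 13-protein targeted plasma panel (accession, description).
DEFAULT_TARGETS = [
    ("P02763", "Alpha-1-acid glycoprotein 1"),
    ("P01009", "Alpha-1-antitrypsin"),
    ("P02647", "Apolipoprotein A-I"),
    ("P06727", "Apolipoprotein A-IV"),
    ("P04114", "Apolipoprotein B-100"),
    ("P02656", "Apolipoprotein C-III"),
    ("P02649", "Apolipoprotein E"),
    ("P02749", "Beta-2-glycoprotein 1"),
    ("P01024", "Complement C3"),
    ("P02671", "Fibrinogen alpha chain"),
    ("P02675", "Fibrinogen beta chain"),
    ("P02679", "Fibrinogen gamma chain"),
    ("P02766", "Transthyretin"),
]


@dataclass
class MrmPanel:
    """Transition list: 2 peptides x 2 fragments per target by default."""

    table: pd.DataFrame  # protein, accession, peptide, fragment, is_internal_control

    def validate(self) -> None:
        need = {"protein", "accession", "peptide", "fragment", "is_internal_control"}
        if not need <= set(self.table.columns):
            raise ValueError(f"panel table must have columns {sorted(need)}")
        per_pep = self.table.groupby(["protein", "peptide"])["fragment"].nunique()
        if (per_pep < 1).any():
            raise ValueError("every peptide needs at least one fragment")

    @property
    def targets(self) -> list[str]:
        t = self.table
        return sorted(t.loc[~t["is_internal_control"], "protein"].unique())

    @property
    def internal_controls(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["is_internal_control"], "protein"].unique())

    @property
    def transitions(self) -> pd.DataFrame:
        return self.table[["protein", "peptide", "fragment"]].drop_duplicates()


def default_panel(
    n_peptides: int = 2, n_fragments: int = 2, with_internal_controls: bool = True
) -> MrmPanel:
    """Build the 13-target plasma panel (plus 2 flagged internal controls).

    Peptide and fragment identifiers are synthetic placeholders
    (``<acc>_pep<k>`` / ``y<j>``); the panel structure — two peptides with two
    fragments each per target — is what the quantification layer relies on.
    """
    rows = []
    entries = list(DEFAULT_TARGETS)
    if with_internal_controls:
        entries += [("IC_A", "Internal control A (synthetic)"),
                    ("IC_B", "Internal control B (synthetic)")]
    for acc, desc in entries:
        is_ic = acc.startswith("IC_")
        for k in range(1, n_peptides + 1):
            for j in range(1, n_fragments + 1):
                rows.append((desc, acc, f"{acc}_pep{k}", f"y{3 + j}", is_ic))
    panel = MrmPanel(pd.DataFrame(
        rows, columns=["protein", "accession", "peptide", "fragment",
                       "is_internal_control"],
    ))
    panel.validate()
    return panel


def panel_for_proteins(proteins: list[str]) -> MrmPanel:
    """Synthetic 2x2 panel over arbitrary protein identifiers (no controls)."""
    rows = [
        (p, p, f"{p}_pep{k}", f"y{3 + j}", False)
        for p in proteins
        for k in (1, 2)
        for j in (1, 2)
    ]
    panel = MrmPanel(pd.DataFrame(
        rows, columns=["protein", "accession", "peptide", "fragment",
                       "is_internal_control"],
    ))
    panel.validate()
    return panel


def qc_normalize_transitions(
    transitions: pd.DataFrame, layout: MrmBatchLayout, qc_scope: str = "batch"
) -> pd.DataFrame:
    """Fragment ratios to the interleaved QC reference injections.

    ``qc_scope="batch"`` (default): the denominator for each
    (batch, protein, peptide, fragment) is the median intensity of that
    fragment over the batch's QC injections.  ``qc_scope="bracket"``
    log-interpolates the two QC injections bracketing each primary injection
    instead, which keeps the residual bias of a slow instrument drift within
    the drift accrued over a single QC period even in long batches.
    Fragments with no usable QC signal in a batch are dropped for that batch
    with a warning.
    """
    if qc_scope not in ("batch", "bracket"):
        raise ValueError(f"unknown qc_scope {qc_scope!r}")
    t = transitions[transitions["intensity"] > 0].copy()
    keys = ["batch_id", "protein", "peptide", "fragment"]
    qc_rows = t[t["sample_id"] == QC]
    if qc_rows.empty:
        raise ValueError("no QC injections found in transition table")
    primary = t[t["sample_id"] != QC].copy()
    if qc_scope == "batch":
        qc_ref = qc_rows.groupby(keys)["intensity"].median().rename("qc_ref")
        primary = primary.merge(qc_ref, on=keys, how="left")
    else:
        denoms = np.full(len(primary), np.nan)
        qc_grouped = {k: g for k, g in qc_rows.groupby(keys)}
        for k, idx in primary.groupby(keys).groups.items():
            g = qc_grouped.get(k)
            if g is None:
                continue
            g = g.sort_values("injection_index")
            denoms[primary.index.get_indexer(idx)] = 2.0 ** np.interp(
                primary.loc[idx, "injection_index"].to_numpy(dtype=float),
                g["injection_index"].to_numpy(dtype=float),
                np.log2(g["intensity"].to_numpy(dtype=float)),
            )
        primary["qc_ref"] = denoms
    n_lost = int(primary["qc_ref"].isna().sum())
    if n_lost:
        log.warning(
            "dropping %d primary measurements lacking QC signal in their batch",
            n_lost,
        )
        primary = primary.dropna(subset=["qc_ref"])
    primary["ratio"] = primary["intensity"] / primary["qc_ref"]
    return primary[["batch_id", "injection_index", "sample_id", "protein",
                    "peptide", "fragment", "ratio"]]


def mrm_protein_rollup(fragment_ratios: pd.DataFrame, panel: MrmPanel) -> QuantResult:
    """Hierarchical mean: fragments -> peptide, peptides -> protein.

    Equal weight per peptide regardless of how many of its fragments survived;
    per-value fragment counts are kept as metadata.
    """
    known = panel.transitions
    fr = fragment_ratios.merge(
        known, on=["protein", "peptide", "fragment"], how="inner"
    )
    pep = (
        fr.groupby(["protein", "peptide", "sample_id"], sort=True)["ratio"]
        .agg(ratio="mean", n_fragments="size")
        .reset_index()
    )
    prot = (
        pep.groupby(["protein", "sample_id"], sort=True)
        .agg(ratio=("ratio", "mean"), n_fragments=("n_fragments", "sum"))
        .reset_index()
    )
    abundance = prot.pivot(index="protein", columns="sample_id", values="ratio")
    nfrag = (
        prot.pivot(index="protein", columns="sample_id", values="n_fragments")
        .fillna(0)
        .astype(int)
    )
    return QuantResult(abundance, nfrag)
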