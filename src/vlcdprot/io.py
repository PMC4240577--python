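"""CSV interchange: every table carries a header comment with seed and version."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .design import (
    ITRAQ_CHANNELS,
    MrmBatchLayout,
    PlexLayout,
    Sample,
    StudyDesign,
    Subject,
)


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# vlcdprot {__version__} seed={seed}\n")
        df.to_csv(fh, index=index)
    return path


def read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def design_to_frame(design: StudyDesign) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.subject_id, s.group, s.timepoint) for s in design.samples],
        columns=["sample_id", "subject_id", "group", "timepoint"],
    )


def design_from_frame(frame: pd.DataFrame) -> StudyDesign:
    subjects = [
        Subject(sid, grp)
        for sid, grp in frame[["subject_id", "group"]].drop_duplicates().itertuples(
            index=False
        )
    ]
    samples = [
        Sample(r.sample_id, r.subject_id, r.group, r.timepoint)
        for r in frame.itertuples(index=False)
    ]
    design = StudyDesign(subjects, samples)
    design.validate()
    return design


def itraq_layout_to_frame(layouts: list[PlexLayout]) -> pd.DataFrame:
    rows = [
        (lay.plex_id, chan, lay.channel_map[chan] or "EMPTY")
        for lay in layouts
        for chan in ITRAQ_CHANNELS
    ]
    return pd.DataFrame(rows, columns=["plex_id", "channel", "assignment"])


def itraq_layout_from_frame(frame: pd.DataFrame) -> list[PlexLayout]:
    layouts = []
    for plex_id, chunk in frame.groupby("plex_id", sort=True):
        cmap = {
            int(r.channel): (None if r.assignment == "EMPTY" else r.assignment)
            for r in chunk.itertuples(index=False)
        }
        lay = PlexLayout(plex_id=plex_id, channel_map=cmap)
        lay.validate()
        layouts.append(lay)
    return layouts


def mrm_layout_to_frame(layout: MrmBatchLayout) -> pd.DataFrame:
    rows = [
        (batch_id, idx, inj)
        for batch_id, injections in layout.batches
        for idx, inj in enumerate(injections)
    ]
    df = pd.DataFrame(rows, columns=["batch_id", "injection_index", "assignment"])
    df.attrs["qc_period"] = layout.qc_period
    return df


def mrm_layout_from_frame(frame: pd.DataFrame, qc_period: int = 4) -> MrmBatchLayout:
    batches = []
    for batch_id, chunk in frame.groupby("batch_id", sort=True):
        chunk = chunk.sort_values("injection_index")
        batches.append((batch_id, list(chunk["assignment"])))
    layout = MrmBatchLayout(batches=batches, qc_period=qc_period)
    layout.validate()
    return layout


def reporters_to_long(reporters: pd.DataFrame) -> pd.DataFrame:
    return reporters.melt(
        id_vars=["plex_id", "peptide_id", "spectrum_id"],
        var_name="channel", value_name="intensity",
    ).dropna(subset=["intensity"])


def reporters_from_long(long: pd.DataFrame) -> pd.DataFrame:
    wide = long.pivot_table(
        index=["plex_id", "peptide_id", "spectrum_id"],
        columns="channel", values="intensity", aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    wide.columns = [str(c) for c in wide.columns]
    for chan in ITRAQ_CHANNELS:
        if str(chan) not in wide.columns:
            wide[str(chan)] = float("nan")
    return wide[["plex_id", "peptide_id", "spectrum_id"]
                + [str(c) for c in ITRAQ_CHANNELS]]


def abundance_to_long(abundance: pd.DataFrame, counts: pd.DataFrame | None,
                      value_name: str = "ratio") -> pd.DataFrame:
    long = (abundance.rename_axis("protein_group")
            .reset_index()
            .melt(id_vars="protein_group", var_name="sample_id",
                  value_name=value_name)
            .dropna(subset=[value_name]))
    if counts is not None:
        c = (counts.rename_axis("protein_group").reset_index()
             .melt(id_vars="protein_group", var_name="sample_id",
                   value_name="n_support"))
        long = long.merge(c, on=["protein_group", "sample_id"], how="left")
    return long


def abundance_from_long(long: pd.DataFrame, value_name: str = "ratio") -> pd.DataFrame:
    return long.pivot(index="protein_group", columns="sample_id", values=value_name)
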