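"""Study design and acquisition layouts.

The study compares obese type-2-diabetes patients sampled before and after a
16-week very-low-calorie diet (half of them with an added exercise program)
against lean and obese control subjects sampled once.  Patient samples are
profiled by 8-plex iTRAQ (six primary channels plus two pooled-reference QC
channels per plex); all samples are profiled by targeted MRM in acquisition
batches with QC reference injections interleaved between primary samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# Subject groups
T2DM_EX = "T2DM_EX"          # patients: VLCD + exercise arm
T2DM_ONLY = "T2DM_ONLY"      # patients: VLCD only
OBESE_CTRL = "OBESE_CTRL"
LEAN_CTRL = "LEAN_CTRL"
GROUPS = (T2DM_EX, T2DM_ONLY, OBESE_CTRL, LEAN_CTRL)
PATIENT_GROUPS = (T2DM_EX, T2DM_ONLY)

# Timepoints
BASELINE = "BASELINE"
WEEK16 = "WEEK16"
SINGLE = "SINGLE"

# iTRAQ 8-plex reporter channels; 113 and 117 always carry the QC pool.
ITRAQ_CHANNELS = (113, 114, 115, 116, 117, 118, 119, 121)
QC_CHANNELS = (113, 117)
PRIMARY_CHANNELS = tuple(c for c in ITRAQ_CHANNELS if c not in QC_CHANNELS)

QC = "QC"           # sentinel sample id for pooled-reference slots
EMPTY = None        # flagged empty channel in a padded plex


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str


@dataclass(frozen=True)
class Sample:
    sample_id: str
    subject_id: str
    group: str
    timepoint: str


@dataclass
class StudyDesign:
    subjects: list[Subject]
    samples: list[Sample]

    @property
    def arm_sizes(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for s in self.subjects:
            out[s.group] += 1
        return out

    @property
    def patient_samples(self) -> list[Sample]:
        return [s for s in self.samples if s.group in PATIENT_GROUPS]

    @property
    def control_samples(self) -> list[Sample]:
        return [s for s in self.samples if s.group not in PATIENT_GROUPS]

    def sample(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    @property
    def _by_id(self) -> dict[str, Sample]:
        return {s.sample_id: s for s in self.samples}

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids")
        per_subject: dict[str, list[Sample]] = {}
        for s in self.samples:
            per_subject.setdefault(s.subject_id, []).append(s)
        for subj in self.subjects:
            obs = per_subject.get(subj.subject_id, [])
            if subj.group in PATIENT_GROUPS:
                tps = sorted(s.timepoint for s in obs)
                if tps != sorted([BASELINE, WEEK16]):
                    raise ValueError(
                        f"patient {subj.subject_id} must have exactly "
                        f"BASELINE and WEEK16 samples, got {tps}"
                    )
            else:
                if [s.timepoint for s in obs] != [SINGLE]:
                    raise ValueError(
                        f"control {subj.subject_id} must have exactly one "
                        "SINGLE sample"
                    )


_PREFIX = {T2DM_EX: "EX", T2DM_ONLY: "VO", OBESE_CTRL: "OB", LEAN_CTRL: "LN"}


def build_study_design(
    n_ex: int = 13, n_only: int = 14, n_obese: int = 27, n_lean: int = 27
) -> StudyDesign:
    """Construct the two-arm intervention design with matched controls.

    Defaults reproduce the study cohort: 27 patients (13 VLCD+exercise,
    14 VLCD-only) sampled at baseline and week 16, plus 27 obese and 27 lean
    controls sampled once — 81 subjects, 108 samples.
    """
    counts = {T2DM_EX: n_ex, T2DM_ONLY: n_only, OBESE_CTRL: n_obese, LEAN_CTRL: n_lean}
    for g, n in counts.items():
        if n < 0:
            raise ValueError(f"negative subject count for {g}: {n}")
    subjects: list[Subject] = []
    samples: list[Sample] = []
    for group in GROUPS:
        for i in range(1, counts[group] + 1):
            sid = f"{_PREFIX[group]}{i:02d}"
            subjects.append(Subject(sid, group))
            if group in PATIENT_GROUPS:
                samples.append(Sample(f"{sid}_T0", sid, group, BASELINE))
                samples.append(Sample(f"{sid}_T16", sid, group, WEEK16))
            else:
                samples.append(Sample(f"{sid}_S", sid, group, SINGLE))
    design = StudyDesign(subjects, samples)
    design.validate()
    return design


@dataclass
class PlexLayout:
    """One 8-plex iTRAQ experiment: channel -> sample id, QC, or flagged empty."""

    plex_id: str
    channel_map: dict[int, str | None]

    def validate(self) -> None:
        if set(self.channel_map) != set(ITRAQ_CHANNELS):
            raise ValueError("plex must map all 8 reporter channels")
        for c in QC_CHANNELS:
            if self.channel_map[c] != QC:
                raise ValueError(f"channel {c} must carry the QC pool")
        primaries = [self.channel_map[c] for c in PRIMARY_CHANNELS]
        filled = [p for p in primaries if p not in (QC, EMPTY)]
        if len(filled) != len(set(filled)):
            raise ValueError("a sample may occupy at most one channel per plex")

    @property
    def primary_samples(self) -> dict[int, str]:
        return {
            c: s
            for c, s in self.channel_map.items()
            if c in PRIMARY_CHANNELS and s not in (QC, EMPTY)
        }


def build_itraq_layout(
    design: StudyDesign, seed: int, pair_timepoints: bool = True
) -> list[PlexLayout]:
    """Assign the patient samples to 8-plex experiments.

    Each plex carries six primary samples (channels 114/115/116/118/119/121)
    and the QC pool in channels 113 and 117.  By default a subject's two
    timepoints are co-located in one plex so plex effects cancel from the
    within-subject contrast; ``pair_timepoints=False`` scrambles samples
    individually to stress-test normalization.  A final incomplete plex is
    padded with flagged empty channels.
    """
    rng = np.random.default_rng(seed)
    psamples = design.patient_samples
    if pair_timepoints:
        subj_ids = sorted({s.subject_id for s in psamples})
        rng.shuffle(subj_ids)
        by_subj = {sid: [] for sid in subj_ids}
        for s in psamples:
            by_subj[s.subject_id].append(s.sample_id)
        ordered: list[str] = []
        for sid in subj_ids:
            ordered.extend(sorted(by_subj[sid]))
    else:
        ordered = sorted(s.sample_id for s in psamples)
        rng.shuffle(ordered)

    n_plex = max(1, math.ceil(len(ordered) / 6)) if ordered else 0
    layouts: list[PlexLayout] = []
    for p in range(n_plex):
        block = ordered[6 * p : 6 * (p + 1)]
        block = block + [EMPTY] * (6 - len(block))
        cmap: dict[int, str | None] = {c: QC for c in QC_CHANNELS}
        for chan, sample_id in zip(PRIMARY_CHANNELS, block):
            cmap[chan] = sample_id
        layout = PlexLayout(plex_id=f"plex{p + 1:02d}", channel_map=cmap)
        layout.validate()
        layouts.append(layout)
    return layouts


@dataclass
class MrmBatchLayout:
    """MRM acquisition schedule: ordered injections per batch with QC interleaving."""

    batches: list[tuple[str, list[str]]]
    qc_period: int = 4

    def validate(self) -> None:
        seen: list[str] = []
        for _, injections in self.batches:
            run = 0
            for inj in injections:
                if inj == QC:
                    run = 0
                else:
                    run += 1
                    seen.append(inj)
                if run > self.qc_period:
                    raise ValueError(
                        f"more than {self.qc_period} consecutive primary injections"
                    )
        if len(seen) != len(set(seen)):
            raise ValueError("a primary sample may be injected only once")

    @property
    def primary_injections(self) -> list[tuple[str, int, str]]:
        """(batch_id, injection_index, sample_id) for primary injections."""
        out = []
        for batch_id, injections in self.batches:
            for idx, inj in enumerate(injections):
                if inj != QC:
                    out.append((batch_id, idx, inj))
        return out


def build_mrm_layout(
    design: StudyDesign, n_batches: int = 3, qc_period: int = 4, seed: int = 0
) -> MrmBatchLayout:
    """Schedule every study sample once across MRM acquisition batches.

    Each batch opens with a QC reference injection and a QC injection follows
    every ``qc_period`` primary samples, so no primary injection is more than
    one period away from a bracketing QC.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if qc_period < 1:
        raise ValueError("qc_period must be >= 1")
    rng = np.random.default_rng(seed)
    order = sorted(s.sample_id for s in design.samples)
    rng.shuffle(order)
    per_batch = [len(chunk) for chunk in np.array_split(np.arange(len(order)), n_batches)]
    batches: list[tuple[str, list[str]]] = []
    pos = 0
    for b, n in enumerate(per_batch):
        block = order[pos : pos + n]
        pos += n
        injections: list[str] = [QC]
        for i in range(0, len(block), qc_period):
            injections.extend(block[i : i + qc_period])
            injections.append(QC)
        if not block:
            injections = []
        batches.append((f"batch{b + 1}", injections))
    layout = MrmBatchLayout(batches=batches, qc_period=qc_period)
    layout.validate()
    return layout


def design_frame(design: StudyDesign):
    """Sample annotation as a pandas DataFrame (sample_id, subject_id, group, timepoint)."""
    import pandas as pd

    return pd.DataFrame(
        [(s.sample_id, s.subject_id, s.group, s.timepoint) for s in design.samples],
        columns=["sample_id", "subject_id", "group", "timepoint"],
    )
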