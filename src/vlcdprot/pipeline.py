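"""End-to-end pipeline: simulate -> infer -> quantify -> filter -> model ->
compare -> classify, with all tables written to an output directory.

Configuration is a nested dict (typically loaded from YAML); unspecified
fields fall back to the study defaults.  All randomness derives from one
master seed.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .design import (
    build_itraq_layout,
    build_mrm_layout,
    build_study_design,
)
from .inference import build_incidence, infer_protein_groups
from .itraq import (
    complete_case_filter,
    compute_peptide_ratios,
    genorm_normalize,
    genorm_stability,
    rollup_protein_ratios,
)
from .markers import classify_markers, comparison_graph_dot, pairwise_comparisons
from .mrm import default_panel, mrm_protein_rollup, panel_for_proteins, qc_normalize_transitions
from .simulate import (
    EffectConfig,
    default_protein_names,
    make_peptide_map,
    simulate_itraq_intensities,
    simulate_mrm_intensities,
    simulate_truth,
)
from .stats import EXERCISE_RULE, VLCD_RULE, fit_vlcd_models, flag_significant

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "simulation": {
        "arms": {"t2dm_ex": 13, "t2dm_only": 14, "obese": 27, "lean": 27},
        "n_proteins": 100,
        # per marker class: how many proteins carry the effect and its size
        # (log2 units); explicit {protein: effect} mappings are also accepted
        "planted": {
            "diet": {"n": 5, "effect": -0.8},
            "diabetes": {"n": 5, "effect": 0.8},
            "obesity": {"n": 5, "effect": 0.8},
            "exercise": {"n": 0, "effect": 0.0},
        },
        "noise": {},              # overrides for EffectConfig fields
        "itraq": {"enabled": True, "mean_peptides": 3.0, "n_spectra": 1,
                  "pair_timepoints": True},
        "mrm": {"enabled": True, "n_batches": 3, "qc_period": 4, "drift": 1.0,
                "use_default_panel": False},
        "internal_controls": [],
    },
    "analysis": {
        "genorm": {"v_threshold": 0.15, "floor": 3, "cap": 10},
        "alpha": 0.05,
        "alpha_bh_vlcd": 0.10,
        "log2_scale": False,
    },
}


def merged_config(user: dict | None) -> dict:
    def merge(base, over):
        out = copy.deepcopy(base)
        for k, v in (over or {}).items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    return merge(DEFAULT_CONFIG, user or {})


def planted_effect_config(sim_cfg: dict, proteins: list[str]) -> EffectConfig:
    """Translate the planted-effects config block into an EffectConfig."""
    cfg = EffectConfig(n_proteins=len(proteins), **(sim_cfg.get("noise") or {}))
    cursor = 0
    for cls in ("diet", "diabetes", "obesity", "exercise"):
        spec = (sim_cfg.get("planted") or {}).get(cls, {})
        target = getattr(cfg, cls)
        if spec and "n" not in spec:
            target.update({str(k): float(v) for k, v in spec.items()})
        else:
            n = int(spec.get("n", 0))
            eff = float(spec.get("effect", 0.0))
            if cls == "exercise":
                # interaction effects ride on the diet-planted proteins when
                # none are named explicitly
                chosen = proteins[:n]
            else:
                chosen = proteins[cursor:cursor + n]
                cursor += n
            for g in chosen:
                target[g] = eff
    return cfg


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: dict | None, seed: int, outdir: str | Path,
                 simulate_only: bool = False) -> dict:
    """Execute the full study pipeline on synthetic data; returns the summary."""
    cfg = merged_config(config)
    sim, ana = cfg["simulation"], cfg["analysis"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.FileHandler(outdir / "run.log", mode="w")]
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for h in handlers:
        h.setFormatter(fmt)
        logging.getLogger("vlcdprot").addHandler(h)
    try:
        return _run(cfg, sim, ana, seed, outdir, simulate_only)
    finally:
        for h in handlers:
            logging.getLogger("vlcdprot").removeHandler(h)
            h.close()


def _run(cfg: dict, sim: dict, ana: dict, seed: int, outdir: Path,
         simulate_only: bool = False) -> dict:
    log.info("vlcdprot %s starting pipeline, master seed %d", __version__, seed)
    s_truth, s_itraq_lay, s_mrm_lay, s_itraq, s_mrm, s_map = _subseeds(seed, 6)

    arms = sim["arms"]
    design = build_study_design(arms["t2dm_ex"], arms["t2dm_only"],
                                arms["obese"], arms["lean"])
    io.write_csv(io.design_to_frame(design), outdir / "annotation.csv", seed)

    proteins = default_protein_names(int(sim["n_proteins"]))
    effect_cfg = planted_effect_config(sim, proteins)
    truth = simulate_truth(design, effect_cfg, s_truth, proteins)
    truth_frame = pd.DataFrame({
        "protein": proteins,
        "mu_log2": truth.mu.values,
        "diet_effect": truth.diet_effect.values,
        "diabetes_effect": truth.diabetes_effect.values,
        "obesity_effect": truth.obesity_effect.values,
        "exercise_effect": truth.exercise_effect.values,
        "marker_class": truth.marker_class().values,
    })
    io.write_csv(truth_frame, outdir / "truth.csv", seed)

    summary: dict = {
        "version": __version__,
        "seed": seed,
        "design": {
            "n_subjects": len(design.subjects),
            "n_samples": len(design.samples),
            "n_patient_samples": len(design.patient_samples),
            "arm_sizes": design.arm_sizes,
        },
    }

    if sim["itraq"]["enabled"]:
        summary["itraq"] = _run_itraq(design, truth, sim, ana, seed,
                                      (s_itraq_lay, s_itraq, s_map), outdir,
                                      simulate_only)
    if sim["mrm"]["enabled"]:
        summary["mrm"] = _run_mrm(design, truth, sim, ana, seed,
                                  (s_mrm_lay, s_mrm), outdir, simulate_only)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline finished")
    return summary


def _run_itraq(design, truth, sim, ana, seed, seeds, outdir,
               simulate_only: bool = False) -> dict:
    s_lay, s_int, s_map = seeds
    it = sim["itraq"]
    layouts = build_itraq_layout(design, s_lay,
                                 pair_timepoints=it["pair_timepoints"])
    io.write_csv(io.itraq_layout_to_frame(layouts), outdir / "itraq_layout.csv", seed)
    peptide_map = make_peptide_map(truth.proteins, s_map,
                                   mean_peptides=it["mean_peptides"],
                                   shared_fraction=it.get("shared_fraction", 0.0))
    io.write_csv(peptide_map, outdir / "peptide_map.csv", seed)
    reporters = simulate_itraq_intensities(layouts, truth, peptide_map, design,
                                           s_int, n_spectra=it["n_spectra"])
    io.write_csv(io.reporters_to_long(reporters),
                 outdir / "reporter_intensities.csv", seed)
    base = {
        "n_plexes": len(layouts),
        "n_primary_slots": sum(len(l.primary_samples) for l in layouts),
        "n_qc_slots": 2 * len(layouts),
    }
    if simulate_only:
        return base

    abundance, state, counts, results = quantify_and_model_itraq(
        reporters, layouts, peptide_map, design, ana,
        internal_controls=sim.get("internal_controls") or [],
    )
    io.write_csv(io.abundance_to_long(abundance, None),
                 outdir / "itraq_abundance.csv", seed)
    genorm_frame = pd.DataFrame({
        "protein_group": state.m_values.index,
        "stability_m": state.m_values.values,
        "is_reference": [g in set(state.reference_set) for g in state.m_values.index],
    })
    io.write_csv(genorm_frame, outdir / "genorm_state.csv", seed)
    io.write_csv(results.reset_index(names="protein_group"),
                 outdir / "model_results.csv", seed)

    n_up = int(((results["significant_vlcd"]) & (results["direction_vlcd"] == "up")).sum())
    n_down = int(((results["significant_vlcd"]) & (results["direction_vlcd"] == "down")).sum())
    return base | {
        "n_proteins_total": counts.n_total,
        "n_proteins_complete": counts.n_complete,
        "n_proteins_analyzed": counts.n_analyzed,
        "n_significant_vlcd": n_up + n_down,
        "n_vlcd_up": n_up,
        "n_vlcd_down": n_down,
        "n_significant_exercise_raw": int(results["significant_exercise"].sum()),
        "genorm_references": list(state.reference_set),
    }


def quantify_and_model_itraq(reporters, layouts, peptide_map, design, ana,
                             internal_controls=()):
    """iTRAQ quantification + modelling stages shared by pipeline and CLI."""
    pep_ratios = compute_peptide_ratios(reporters, layouts)
    groups = infer_protein_groups(build_incidence(peptide_map))
    quant = rollup_protein_ratios(pep_ratios, groups)
    gcfg = ana["genorm"]
    state = genorm_stability(quant.abundance)
    normalized, state = genorm_normalize(
        quant.abundance, state, v_threshold=gcfg["v_threshold"],
        floor=gcfg["floor"], cap=gcfg["cap"],
    )
    analyzed, counts = complete_case_filter(normalized, design,
                                            list(internal_controls))
    results = fit_vlcd_models(analyzed, design, log2_scale=ana["log2_scale"])
    vlcd = flag_significant(results, VLCD_RULE, alpha_raw=ana["alpha"],
                            alpha_bh=ana["alpha_bh_vlcd"])
    exer = flag_significant(results, EXERCISE_RULE, alpha_raw=ana["alpha"])
    results = results.assign(
        significant_vlcd=vlcd["significant"],
        direction_vlcd=vlcd["direction"],
        significant_exercise=exer["significant"],
        direction_exercise=exer["direction"],
    )
    return analyzed, state, counts, results


def _run_mrm(design, truth, sim, ana, seed, seeds, outdir,
             simulate_only: bool = False) -> dict:
    s_lay, s_int = seeds
    mc = sim["mrm"]
    layout = build_mrm_layout(design, n_batches=mc["n_batches"],
                              qc_period=mc["qc_period"], seed=s_lay)
    io.write_csv(io.mrm_layout_to_frame(layout), outdir / "mrm_layout.csv", seed)
    if mc["use_default_panel"]:
        panel = default_panel()
    else:
        panel = panel_for_proteins(truth.proteins)
    io.write_csv(panel.table, outdir / "mrm_panel.csv", seed)
    transitions = simulate_mrm_intensities(layout, truth, panel.transitions,
                                           design, s_int,
                                           drift_per_injection=mc["drift"])
    io.write_csv(transitions, outdir / "mrm_transitions.csv", seed)
    base = {
        "n_batches": len(layout.batches),
        "n_primary_injections": len(layout.primary_injections),
        "n_targets": len(panel.targets),
        "n_internal_controls": len(panel.internal_controls),
    }
    if simulate_only:
        return base

    abundance, comparisons, categories = quantify_and_classify_mrm(
        transitions, layout, panel, design, ana,
    )
    io.write_csv(io.abundance_to_long(abundance, None),
                 outdir / "mrm_abundance.csv", seed)
    io.write_csv(comparisons, outdir / "comparisons.csv", seed)
    io.write_csv(categories.rename_axis("protein").reset_index(),
                 outdir / "marker_categories.csv", seed)

    dot_dir = outdir / "dot"
    dot_dir.mkdir(exist_ok=True)
    for prot, chunk in comparisons.groupby("protein"):
        (dot_dir / f"{prot}.dot").write_text(comparison_graph_dot(chunk, prot))

    tallies = categories.value_counts().to_dict()
    out = base | {
        "category_tallies": {str(k): int(v) for k, v in tallies.items()},
    }
    # confusion matrix against the planted truth
    planted = truth.marker_class()
    shared = [p for p in categories.index if p in planted.index]
    if shared:
        conf = pd.crosstab(planted.loc[shared], categories.loc[shared])
        out["confusion_planted_vs_called"] = {
            str(row): {str(c): int(v) for c, v in conf.loc[row].items()}
            for row in conf.index
        }
    return out


def quantify_and_classify_mrm(transitions, layout, panel, design, ana):
    """MRM quantification + classification stages shared by pipeline and CLI."""
    ratios = qc_normalize_transitions(transitions, layout)
    quant = mrm_protein_rollup(ratios, panel)
    comparisons = pairwise_comparisons(quant.abundance, design)
    categories = classify_markers(comparisons, alpha=ana["alpha"])
    return quant.abundance, comparisons, categories
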