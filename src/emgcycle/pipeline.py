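"""End-to-end workflows: simulate a study, analyze it, summarize it.

``simulate`` writes raw synthetic trials (CSV, one column per muscle) plus
ground-truth sidecars for resistance levels 2–5, three trials per level, as
in the study protocol.  ``analyze`` runs the full chain — envelopes, session
standardization, cycle segmentation, time normalization, phase
factorization, contribution and stability metrics, pairwise rank tests —
and writes tidy tables.  ``report`` turns the tables into per-condition
figures and summary CSVs.  Everything is deterministic given the seeds in
the configuration, and every table carries the hash of the resolved
configuration that produced it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .averaging import average_cycles, merge_normalized, normalize_cycles
from .config import PipelineConfig, config_hash
from .decomposition import (
    OrderSelectionError,
    SynergyModel,
    nmf,
    normalize_model,
    phase_assignment,
    select_order,
)
from .metrics import (
    cycle_reference,
    per_cycle_models,
    relative_contribution,
    stability_from_models,
)
from .preprocessing import preprocess, standardize_session
from .segmentation import composite_envelope, detect_boundaries, segment
from .stats import pairwise_tests, results_to_frame
from .synthetic import (
    apply_resistance_effect,
    generate_trial,
    read_session_csv,
    write_ground_truth_yaml,
    write_session_csv,
)

__all__ = ["simulate", "analyze", "report", "LEVELS", "TRIALS_PER_LEVEL"]

logger = logging.getLogger("emgcycle")

LEVELS = (2, 3, 4, 5)
TRIALS_PER_LEVEL = 3

_TRIAL_RE = re.compile(r"level(\d+)_trial(\d+)\.csv$")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate(config: PipelineConfig, out_dir, seed: int | None = None) -> list[Path]:
    """Write one simulated session: levels 2–5, three trials each.

    Returns the written trial paths.  A ``manifest.yaml`` lists every file
    with its checksum, the config hash, and per-trial metadata.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = config.synth if seed is None else dataclasses.replace(config.synth, seed=seed)
    written: list[Path] = []
    entries = []
    for level in LEVELS:
        level_cfg = apply_resistance_effect(base, level)
        for t in range(TRIALS_PER_LEVEL):
            trial_id = level * 10 + t
            session, truth = generate_trial(level_cfg, trial_id=trial_id)
            stem = f"level{level}_trial{t}"
            csv_path = out / f"{stem}.csv"
            truth_path = out / f"{stem}_truth.yaml"
            write_session_csv(session, csv_path)
            write_ground_truth_yaml(truth, truth_path)
            written.append(csv_path)
            entries.append(
                {
                    "file": csv_path.name,
                    "truth": truth_path.name,
                    "sha256": _sha256(csv_path),
                    "truth_sha256": _sha256(truth_path),
                    "level": level,
                    "trial": t,
                    "fs_hz": float(level_cfg.fs_hz),
                }
            )
            logger.info("wrote %s", csv_path.name)
    manifest = {
        "config_hash": config_hash(config),
        "seed": int(base.seed),
        "trials": entries,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return written


def _discover_trials(in_dir: Path) -> list[dict]:
    manifest_path = in_dir / "manifest.yaml"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        return sorted(manifest["trials"], key=lambda e: (e["level"], e["trial"]))
    entries = []
    for path in sorted(in_dir.glob("level*_trial*.csv")):
        match = _TRIAL_RE.search(path.name)
        if match:
            entries.append(
                {
                    "file": path.name,
                    "level": int(match.group(1)),
                    "trial": int(match.group(2)),
                    "fs_hz": 1500.0,
                }
            )
    return entries


def _condition_reference(
    M: np.ndarray, config: PipelineConfig
) -> tuple[SynergyModel, int]:
    nc = config.nmf
    if nc.order is None:
        try:
            order = select_order(
                M,
                vaf_threshold=nc.vaf_threshold,
                n_max=nc.n_max,
                seed=nc.seed,
                restarts=nc.restarts,
                max_iter=nc.max_iter,
                tol=nc.tol,
            )
        except OrderSelectionError as exc:
            logger.warning("order selection fell back to best found: %s", exc)
            order = exc.best_order
    else:
        order = nc.order
    model = nmf(
        M, order, seed=nc.seed, restarts=nc.restarts, max_iter=nc.max_iter, tol=nc.tol
    )
    return model, order


def analyze(in_dir, config: PipelineConfig, out_dir) -> dict[str, Path]:
    """Run the full analysis over a directory of trial CSVs.

    Writes six tidy tables (synergy weights, synergy activations, model
    fits, per-cycle phase contributions, per-trial stability indices,
    pairwise comparisons) plus a run log with all resolved parameters.
    """
    config.validate()
    in_path = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    entries = _discover_trials(in_path)
    if not entries:
        raise FileNotFoundError(f"no trial CSVs found under {in_path}")

    # --- envelopes, standardized over the whole session -------------------
    sessions = []
    for e in entries:
        sessions.append(
            read_session_csv(
                in_path / e["file"],
                fs_hz=float(e.get("fs_hz", 1500.0)),
                condition_label=int(e["level"]),
                trial_id=int(e["trial"]),
            )
        )
    envelopes = [
        preprocess(
            s,
            highpass_hz=config.preprocessing.highpass_hz,
            lowpass_hz=config.preprocessing.lowpass_hz,
            standardize=False,
        )
        for s in sessions
    ]
    envelopes = standardize_session(envelopes)

    # --- segmentation and time normalization, per trial -------------------
    normalized = []  # (level, trial, NormalizedCycleSet)
    failures = []
    for env in envelopes:
        try:
            series = composite_envelope(env)
            bounds = detect_boundaries(
                series,
                env.fs_hz,
                min_period_s=config.segmentation.min_period_s,
                prominence_frac=config.segmentation.prominence_frac,
            )
            cycles = segment(env, bounds)
            ncs = normalize_cycles(
                cycles,
                t_norm=config.averaging.t_norm,
                onset_frac=config.averaging.onset_frac,
            )
            normalized.append((env.condition_label, env.trial_id, ncs))
        except ValueError as exc:  # preserve partial results, log provenance
            failures.append(
                {"level": env.condition_label, "trial": env.trial_id, "error": str(exc)}
            )
            logger.warning(
                "trial level=%s trial=%s failed: %s",
                env.condition_label,
                env.trial_id,
                exc,
            )
    if not normalized:
        raise ValueError("every trial failed segmentation")

    levels = sorted({lvl for lvl, _, _ in normalized})
    t_norm = config.averaging.t_norm
    w_rows, h_rows, model_rows, contrib_rows, stab_rows = [], [], [], [], []
    avg_rows = []
    baseline_ref = None
    muscle_labels = normalized[0][2].muscle_labels

    for level in levels:
        sets = [(t, ncs) for lvl, t, ncs in normalized if lvl == level]
        tensor = np.concatenate([ncs.tensor for _, ncs in sets], axis=0)
        # concatenate time-normalized cycles along time: muscle x (cycles * T)
        M = tensor.transpose(1, 0, 2).reshape(tensor.shape[1], -1)
        model, order = _condition_reference(M, config)
        model = normalize_model(model)
        # keep phase numbering consistent across conditions
        cyc_ref = cycle_reference(model, t_norm)
        if baseline_ref is None:
            baseline_ref = cyc_ref
        else:
            perm = phase_assignment(cyc_ref, baseline_ref)
            model = dataclasses.replace(model, W=model.W[:, perm], H=model.H[perm, :])
            cyc_ref = cycle_reference(model, t_norm)

        for i in range(model.n_phases):
            for m, label in enumerate(muscle_labels):
                w_rows.append(
                    {
                        "condition": level,
                        "phase": i + 1,
                        "muscle": label,
                        "weight": model.W[m, i],
                        "config_hash": chash,
                    }
                )
            for tau in range(t_norm):
                h_rows.append(
                    {
                        "condition": level,
                        "phase": i + 1,
                        "tau": tau,
                        "activation": cyc_ref.H[i, tau],
                        "config_hash": chash,
                    }
                )
        avg = average_cycles(merge_normalized([ncs for _, ncs in sets]))
        for m, label in enumerate(muscle_labels):
            for tau in range(t_norm):
                avg_rows.append(
                    {
                        "condition": level,
                        "muscle": label,
                        "tau": tau,
                        "value": avg.matrix[m, tau],
                        "config_hash": chash,
                    }
                )
        model_rows.append(
            {
                "condition": level,
                "n_phases": model.n_phases,
                "selected_order": order,
                "vaf": model.vaf,
                "converged": bool(model.converged),
                "n_iter": model.n_iter,
                "n_cycles": tensor.shape[0],
                "config_hash": chash,
            }
        )

        for trial, ncs in sets:
            models = per_cycle_models(
                ncs,
                model,
                seed=config.nmf.seed * 1000 + level * 100 + trial * 10,
                restarts=config.stability.restarts,
                max_iter=config.stability.max_iter,
                tol=config.stability.tol,
                mode=config.stability.mode,
            )
            for k, cm in enumerate(models):
                C = relative_contribution(cm.W, cm.H).C
                for i in range(cm.n_phases):
                    contrib_rows.append(
                        {
                            "condition": level,
                            "trial": trial,
                            "cycle": k,
                            "phase": i + 1,
                            "metric": "contribution",
                            "value": C[i],
                            "config_hash": chash,
                        }
                    )
            stab = stability_from_models(models)
            for i in range(stab.temporal.size):
                for name, arr in (("temporal", stab.temporal), ("spatial", stab.spatial)):
                    stab_rows.append(
                        {
                            "condition": level,
                            "trial": trial,
                            "phase": i + 1,
                            "metric": name,
                            "value": arr[i],
                            "config_hash": chash,
                        }
                    )

    contrib_df = pd.DataFrame(contrib_rows)
    stab_df = pd.DataFrame(stab_rows)

    # --- pairwise rank tests across conditions ----------------------------
    comparison_frames = []
    n_phases = int(contrib_df["phase"].max()) if len(contrib_df) else 0
    for i in range(1, n_phases + 1):
        sub = contrib_df[contrib_df["phase"] == i].drop(columns=["metric"])
        if sub["condition"].nunique() >= 2:
            res = pairwise_tests(
                sub,
                metric_name=f"contribution_phase{i}",
                paired=config.stats.paired,
                holm=config.stats.holm,
            )
            comparison_frames.append(results_to_frame(res))
        for name in ("temporal", "spatial"):
            ssub = stab_df[
                (stab_df["phase"] == i) & (stab_df["metric"] == name)
            ].drop(columns=["metric"])
            if len(ssub) and ssub["condition"].nunique() >= 2:
                res = pairwise_tests(
                    ssub,
                    metric_name=f"{name}_stability_phase{i}",
                    paired=config.stats.paired,
                    holm=config.stats.holm,
                )
                comparison_frames.append(results_to_frame(res))
    comparisons = (
        pd.concat(comparison_frames, ignore_index=True)
        if comparison_frames
        else pd.DataFrame()
    )
    if len(comparisons):
        comparisons["config_hash"] = chash

    paths = {
        "synergy_weights": out / "synergy_weights.csv",
        "synergy_activations": out / "synergy_activations.csv",
        "models": out / "models.csv",
        "average_cycle": out / "average_cycle.csv",
        "contribution": out / "contribution.csv",
        "stability": out / "stability.csv",
        "comparisons": out / "comparisons.csv",
    }
    pd.DataFrame(w_rows).to_csv(paths["synergy_weights"], index=False)
    pd.DataFrame(h_rows).to_csv(paths["synergy_activations"], index=False)
    pd.DataFrame(model_rows).to_csv(paths["models"], index=False)
    pd.DataFrame(avg_rows).to_csv(paths["average_cycle"], index=False)
    contrib_df.to_csv(paths["contribution"], index=False)
    stab_df.to_csv(paths["stability"], index=False)
    comparisons.to_csv(paths["comparisons"], index=False)

    log = {
        "config": config.to_dict(),
        "config_hash": chash,
        "inputs": [e["file"] for e in entries],
        "failures": failures,
        "tables": {k: p.name for k, p in paths.items()},
    }
    with open(out / "analyze_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    paths["log"] = out / "analyze_log.yaml"
    return paths


def report(analysis_dir, out_dir=None) -> dict[str, Path]:
    """Per-condition synergy figures plus three summary tables.

    Requires the tables written by :func:`analyze`; raises
    ``FileNotFoundError`` when they are missing.  Temporal activation curves
    in the figures are normalized by their maxima (display convention).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    src = Path(analysis_dir)
    out = Path(out_dir) if out_dir is not None else src / "report"
    needed = ["synergy_weights.csv", "synergy_activations.csv", "contribution.csv",
              "stability.csv", "comparisons.csv"]
    missing = [n for n in needed if not (src / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing analyze outputs in {src}: {missing}")
    out.mkdir(parents=True, exist_ok=True)

    weights = pd.read_csv(src / "synergy_weights.csv")
    acts = pd.read_csv(src / "synergy_activations.csv")
    contrib = pd.read_csv(src / "contribution.csv")
    stab = pd.read_csv(src / "stability.csv")
    comps = pd.read_csv(src / "comparisons.csv")

    written: dict[str, Path] = {}
    for level, wsub in weights.groupby("condition"):
        asub = acts[acts["condition"] == level]
        phases = sorted(wsub["phase"].unique())
        fig, axes = plt.subplots(len(phases), 2, figsize=(9, 2.4 * len(phases)))
        axes = np.atleast_2d(axes)
        for row, phase in enumerate(phases):
            h = asub[asub["phase"] == phase].sort_values("tau")["activation"].to_numpy()
            h = h / h.max() if h.max() > 0 else h
            axes[row, 0].plot(np.linspace(0, 100, h.size), h, color="tab:blue")
            axes[row, 0].set_ylabel(f"phase {phase}")
            axes[row, 0].set_ylim(0, 1.05)
            ww = wsub[wsub["phase"] == phase]
            axes[row, 1].bar(ww["muscle"], ww["weight"], color="tab:orange")
        axes[-1, 0].set_xlabel("cycle (%)")
        fig.suptitle(f"Resistance level {level}")
        fig.tight_layout()
        fig_path = out / f"synergies_level{level}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written[f"figure_level{level}"] = fig_path

    summaries = {
        "contribution_summary": contrib.groupby(["condition", "phase"])["value"]
        .agg(["median", "mean", "std", "count"])
        .reset_index(),
        "stability_summary": stab.groupby(["condition", "phase", "metric"])["value"]
        .agg(["median", "mean", "std", "count"])
        .reset_index(),
        "significance_summary": comps[
            ["metric", "condition_a", "condition_b", "U", "p_value", "significant"]
        ]
        if len(comps)
        else comps,
    }
    for name, frame in summaries.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path
    return written
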