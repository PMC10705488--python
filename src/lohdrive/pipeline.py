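"""End-to-end pipeline: simulate -> call-loh -> call-mut -> stats -> power.

Each stage reads its inputs from and writes its products to ``out_dir`` as
plain text, logs to stderr with a stage prefix, and is skipped when its
outputs already exist (unless forced), so interrupted runs resume cleanly.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .genotypes import GenotypeMatrix
from .lohcall import CorrectionModel, call_events, correct_counts, events_to_frame
from .mutcall import call_de_novo, count_events, merge_complex
from .power import observed_power, theoretical_power
from .rate_stats import bootstrap_ci, conversion_rate, event_rate, permutation_test
from .simulate import SimConfig, build_marker_map, simulate_cohort

__all__ = ["run_pipeline", "cohort_stats", "DEFAULT_CONFIG"]

# Demo-scale defaults: a 1 Mb toy genome that runs end to end in seconds.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "map": {"n_chromosomes": 4, "chrom_lengths": [350_000, 300_000, 200_000, 150_000],
            "mean_spacing": 320},
    "sim": {"loh_rate": 1.76e-2, "generations": 800, "n_lines": 12,
            "rate_multipliers": {"W": 1.0, "C": 1.0, "D": 1.0}},
    "call": {"merge_gap": 10_000, "missing": "transparent"},
    "stats": {"n_boot": 1000, "n_perm": 1000},
    "power": {"mode": "theoretical", "mu": 13.2, "n_lines": 95,
              "effect_grid": [0.15], "alpha": 0.01, "n_sims": 50, "n_perms": 200},
}


def _log(stage: str, msg: str) -> None:
    print(f"[lohdrive:{stage}] {msg}", file=sys.stderr)


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def cohort_stats(
    gm: GenotypeMatrix,
    ev_frame: pd.DataFrame,
    corrected: pd.Series,
    n_boot: int = 1_000,
    n_perm: int = 1_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-founder rate table and permutation comparisons against the first
    founder label (the control)."""
    labels = gm.metadata["founder_label"]
    T = int(gm.metadata["generations"].iloc[0])
    frac = gm.het_fraction_converted()
    rng = np.random.default_rng(seed)
    rate_rows, test_rows = [], []
    counts_by_label = {}
    for label in labels.unique():
        clones = labels.index[labels == label]
        detected = ev_frame.groupby("clone").size().reindex(clones, fill_value=0)
        corr = corrected.reindex(clones, fill_value=0.0)
        counts_by_label[label] = detected
        lo, hi = bootstrap_ci(corr, n_boot=n_boot, seed=rng)
        n = len(clones)
        rate_rows.append({
            "founder": label, "n": n, "detected": int(detected.sum()),
            "corrected": float(corr.sum()),
            "events_per_line": detected.sum() / n,
            "event_rate": event_rate(corr.sum(), n, T),
            "rate_ci_low": event_rate(lo * n, n, T),
            "rate_ci_high": event_rate(hi * n, n, T),
            "conversion_rate": conversion_rate(frac.loc[clones], T),
        })
    ref = labels.unique()[0]
    for label in labels.unique():
        if label == ref:
            continue
        res = permutation_test(counts_by_label[label], counts_by_label[ref],
                               n_perm=n_perm, seed=rng)
        test_rows.append({
            "comparison": f"{label}_vs_{ref}", "statistic": res.statistic,
            "p_value": res.p_value, "n_resamples": res.n_resamples,
        })
    return pd.DataFrame(rate_rows), pd.DataFrame(test_rows)


def _outputs(out_dir: Path) -> dict[str, Path]:
    return {
        "map": out_dir / "marker_map.tsv",
        "genotypes": out_dir / "genotypes.tsv",
        "truth": out_dir / "truth.json",
        "variants": out_dir / "variants.tsv",
        "events": out_dir / "events.bed",
        "corrected": out_dir / "corrected_counts.tsv",
        "mutations": out_dir / "mutations.tsv",
        "rates": out_dir / "rates.tsv",
        "tests": out_dir / "tests.tsv",
        "power": out_dir / "power.tsv",
    }


def run_pipeline(config: dict | None = None, out_dir: str | Path = "lohdrive_run",
                 force: bool = False) -> int:
    """Run all stages; returns a process-style exit status (0 = success)."""
    cfg = _merged(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _outputs(out_dir)
    meta = {"seed": cfg["seed"], "config_hash": lio.config_hash(cfg)}

    try:
        # ---- simulate -----------------------------------------------------
        sim_outputs = [paths["map"], paths["genotypes"], paths["truth"], paths["variants"]]
        if force or not all(p.exists() for p in sim_outputs):
            _log("simulate", "building marker map and simulating cohort")
            mp = build_marker_map(seed=cfg["seed"], **cfg["map"])
            sim_cfg = SimConfig(seed=cfg["seed"], **cfg["sim"])
            gm, truth, variants = simulate_cohort(mp, sim_cfg)
            lio.write_marker_map(mp, paths["map"], meta=meta)
            lio.write_genotypes_tsv(gm, paths["genotypes"], meta=meta)
            lio.write_truth_json(truth, paths["truth"])
            variants.to_csv(paths["variants"], sep="\t", index=False)
            _log("simulate", f"{gm.n_clones} clones, {mp.n_markers} markers")
        else:
            _log("simulate", "outputs exist, skipping (use force=True to rerun)")
            mp = lio.read_marker_map(paths["map"])
            gm = lio.read_genotypes_tsv(paths["genotypes"], mp)
            variants = pd.read_csv(paths["variants"], sep="\t")

        # ---- call-loh -----------------------------------------------------
        if force or not (paths["events"].exists() and paths["corrected"].exists()):
            _log("call-loh", "calling LOH tracts and events")
            events = call_events(gm, merge_gap=cfg["call"]["merge_gap"],
                                 missing=cfg["call"]["missing"])
            lio.write_events_bed(events, paths["events"], meta=meta)
            corrected = correct_counts(events, mp, CorrectionModel(), clones=gm.clones)
            corrected.to_csv(paths["corrected"], sep="\t", header=True)
            _log("call-loh", f"{len(events)} events called")
        else:
            _log("call-loh", "outputs exist, skipping")
            events = None

        # ---- call-mut -----------------------------------------------------
        if force or not paths["mutations"].exists():
            _log("call-mut", "filtering unique variants and merging complex events")
            unique = call_de_novo(variants)
            records = merge_complex(unique)
            records.to_csv(paths["mutations"], sep="\t", index=False)
            _log("call-mut", f"{len(records)} mutations in {count_events(records)} events")

        # ---- stats --------------------------------------------------------
        if force or not (paths["rates"].exists() and paths["tests"].exists()):
            _log("stats", "estimating rates and comparing founders")
            ev_frame = lio.read_events_bed(paths["events"])
            corrected = pd.read_csv(paths["corrected"], sep="\t", index_col=0)["corrected_count"]
            rates, tests = cohort_stats(gm, ev_frame, corrected,
                                        n_boot=cfg["stats"]["n_boot"],
                                        n_perm=cfg["stats"]["n_perm"],
                                        seed=cfg["seed"])
            rates.to_csv(paths["rates"], sep="\t", index=False)
            tests.to_csv(paths["tests"], sep="\t", index=False)

        # ---- power --------------------------------------------------------
        if force or not paths["power"].exists():
            pcfg = cfg["power"]
            _log("power", f"estimating {pcfg['mode']} power")
            rng = np.random.default_rng(cfg["seed"] + 1)
            if pcfg["mode"] == "theoretical":
                curve = theoretical_power(
                    mu=pcfg["mu"], n_lines=pcfg["n_lines"],
                    effect_grid=tuple(pcfg["effect_grid"]), alpha=pcfg["alpha"],
                    n_sims=pcfg["n_sims"], n_perms=pcfg["n_perms"], seed=rng)
            else:
                ev_frame = lio.read_events_bed(paths["events"])
                pooled = ev_frame.groupby("clone").size().reindex(gm.clones, fill_value=0)
                curve = observed_power(
                    pooled.to_numpy(), n_a=pcfg.get("n_a", 79), n_b=pcfg.get("n_b", 67),
                    effect_grid=tuple(pcfg["effect_grid"]), alpha=pcfg["alpha"],
                    n_sims=pcfg["n_sims"], n_perms=pcfg["n_perms"], seed=rng)
            curve.table.to_csv(paths["power"], sep="\t", index=False)
    except FileNotFoundError as err:
        _log("error", f"missing input: {err}")
        return 1
    except Exception as err:  # pragma: no cover - defensive
        _log("error", f"{type(err).__name__}: {err}")
        return 1
    _log("done", f"all products in {out_dir}")
    return 0
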