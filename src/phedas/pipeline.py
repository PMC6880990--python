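"""End-to-end orchestration: config -> ranked results table, plot, run log.

One YAML/JSON config drives the whole screen.  Every effective setting —
null interval on both scales, censoring window, carrier filter, provider
mode, counts at each filtering stage — is echoed into the run log so each
number in the results CSV can be recomputed from recorded inputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CensorWindow,
    aggregate,
    censor_visits,
    load_subjects,
    load_visits,
    match_controls,
)
from .errors import ConfigError
from .novelty import FixtureProvider, LiteratureCounts, NoveltyIndex, fetch_counts
from .screen import PhecodeScreen
from .sgpv import NullInterval, SgpvRanker
from .synthetic_emr import SimConfig, write_cohort
from .vocab import expand_concept_strings, load_concept_tables, load_phecode_map, map_visits, toy_data_path

__all__ = ["validate_config", "run_pipeline", "render_or_plot", "DEFAULTS"]

DEFAULTS = {
    "measure": "binary",
    "null_interval_or": [0.3, 1.5],
    "pi0": 0.5,
    "ci_level": 0.95,
    "min_carriers": 5,
    "provider": "fixture",
    "seed": 0,
    "use_covariates": True,
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(config: dict) -> dict:
    """Fill defaults and enumerate every schema violation at once."""
    cfg = {**DEFAULTS, **config}
    problems = []
    if cfg["measure"] not in ("binary", "count", "duration"):
        problems.append(f"measure must be binary/count/duration, got {cfg['measure']!r}")
    ni = cfg["null_interval_or"]
    if not (isinstance(ni, (list, tuple)) and len(ni) == 2):
        problems.append("null_interval_or must be [lo, hi]")
    elif not (0 < ni[0] < ni[1]):
        problems.append(f"null_interval_or must satisfy 0 < lo < hi, got {ni}")
    if not 0.0 <= cfg["pi0"] <= 1.0:
        problems.append("pi0 must be in [0, 1]")
    if not 0.0 < cfg["ci_level"] < 1.0:
        problems.append("ci_level must be in (0, 1)")
    if cfg["min_carriers"] < 0:
        problems.append("min_carriers must be >= 0")
    if cfg["provider"] not in ("fixture", "live"):
        problems.append("provider must be 'fixture' or 'live'")
    has_files = "visits" in cfg and "subjects" in cfg
    if not has_files and "simulate" not in cfg:
        problems.append("config needs either visits+subjects paths or a simulate block")
    if has_files:
        for key in ("visits", "subjects"):
            if not Path(cfg[key]).exists():
                problems.append(f"missing input file: {key}={cfg[key]}")
    if "window" in cfg:
        w = cfg["window"]
        if w.get("mode") not in ("age_interval", "left_censor", "right_censor"):
            problems.append(f"window.mode invalid: {w.get('mode')!r}")
        try:
            if not float(w.get("lo", 0)) < float(w.get("hi", float("inf"))):
                problems.append("window requires lo < hi")
        except (TypeError, ValueError):
            problems.append("window bounds must be numeric")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return cfg


def _window_from_config(cfg: dict) -> CensorWindow | None:
    if "window" not in cfg:
        return None
    w = cfg["window"]
    hi = w.get("hi", float("inf"))
    return CensorWindow(w["mode"], float(w["lo"]), float("inf") if hi in (None, "inf") else float(hi))


def run_pipeline(config: dict | str | Path, out_dir: str | Path = "phedas_out") -> pd.DataFrame:
    """Run the full screen from a config; write results, plot and run log.

    Returns the association results table (also written to
    ``<out_dir>/results.csv``): one row per screened phecode with OR and CI
    on the odds-ratio scale, SGPV, PPV, PubMed proportion, novelty score and
    NFI, sorted with significant findings first by descending NFI.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "config": _jsonable(cfg), "stages": {}}

    # --- inputs ------------------------------------------------------------
    map_path = cfg.get("phecode_map", toy_data_path("toy_phecode_map.csv"))
    if "simulate" in cfg and not ("visits" in cfg and "subjects" in cfg):
        sim = SimConfig(**{**cfg["simulate"], "seed": cfg["simulate"].get("seed", cfg["seed"])})
        paths = write_cohort(sim, out_dir / "simulated")
        cfg["visits"], cfg["subjects"] = str(paths["visits"]), str(paths["subjects"])
        map_path = paths["phecode_map"]
        log["stages"]["simulated"] = {k: str(v) for k, v in paths.items()}
    pmap = load_phecode_map(map_path)
    visits = load_visits(cfg["visits"])
    subjects = load_subjects(cfg["subjects"])
    log["stages"]["input"] = {
        "visits": len(visits),
        "subjects": len(subjects),
        "cases": int(subjects["is_case"].sum()),
        "phecode_map": str(map_path),
    }

    # --- mapping and censoring --------------------------------------------
    mapped, n_unmapped = map_visits(visits, pmap)
    log["stages"]["mapping"] = {"mapped": len(mapped), "unmapped": n_unmapped}
    window = _window_from_config(cfg)
    if window is not None:
        mapped = censor_visits(mapped, subjects, window)
        log["stages"]["censoring"] = {
            "mode": window.mode, "lo": window.lo, "hi": _jsonable(window.hi),
            "kept": len(mapped),
        }

    # --- optional control matching ----------------------------------------
    if "match" in cfg:
        ratio = int(cfg["match"].get("ratio", 1))
        index_phecode = cfg["match"].get("index_phecode")
        cases = subjects[subjects["is_case"]]
        pool = subjects[~subjects["is_case"]]
        exclusions: set[str] = set()
        if index_phecode:
            exclusions = pmap.exclusion_set(index_phecode, pmap.phecodes)
        carriage = mapped.groupby("subject_id")["phecode"].agg(set).to_dict()
        controls = match_controls(
            cases, pool, ratio=ratio, exclusions=exclusions,
            seed=cfg["seed"], pool_phecodes=carriage,
        )
        subjects = pd.concat([cases, controls.drop(columns="matched_case")],
                             ignore_index=True)
        mapped = mapped[mapped["subject_id"].isin(set(subjects["subject_id"]))]
        log["stages"]["matching"] = {
            "ratio": ratio, "controls_selected": len(controls),
            "exclusion_phecodes": sorted(exclusions),
        }

    # --- aggregate + screen ------------------------------------------------
    matrix = aggregate(mapped, subjects, measure=cfg["measure"],
                       phecodes=sorted(pmap.phecodes))
    screen = PhecodeScreen(
        level=cfg["ci_level"], min_carriers=cfg["min_carriers"],
        use_covariates=cfg["use_covariates"],
    ).fit(matrix)
    log["stages"]["screen"] = {
        "fitted": len(screen.results_), "skipped": len(screen.skipped_),
    }

    # --- sgpv / ppv ---------------------------------------------------------
    null = NullInterval.from_or(*cfg["null_interval_or"])
    log["null_interval"] = {
        "or_scale": list(cfg["null_interval_or"]),
        "log_odds_scale": [null.lo, null.hi],
    }
    ranked = SgpvRanker(
        null_or=tuple(cfg["null_interval_or"]), pi0=cfg["pi0"], level=cfg["ci_level"]
    ).transform(screen.results_)
    log["stages"]["sgpv"] = {
        "significant": int((ranked["sgpv"] == 0.0).sum()),
        "confirmed_null": int((ranked["sgpv"] == 1.0).sum()),
    }

    # --- novelty -------------------------------------------------------------
    counts = _literature_counts(cfg, pmap, ranked["phecode"])
    results = NoveltyIndex(
        counts, restrict_to_significant=cfg.get("novelty_restrict_to_significant", False)
    ).transform(ranked)
    results["label"] = results["phecode"].map(pmap.labels).fillna("")

    # significant rows first, by NFI descending; the rest by phecode
    results = results.sort_values(
        ["nfi", "phecode"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    cols = ["phecode", "label", "or", "or_lo", "or_hi", "theta", "se", "ci_lo",
            "ci_hi", "sgpv", "classification", "ppv", "pubmed_proportion",
            "n_s", "nfi", "separation", "negative_direction", "converged",
            "case_carriers", "control_carriers", "n_used"]
    results = results[[c for c in cols if c in results.columns]]

    results_path = out_dir / "results.csv"
    results.to_csv(results_path, index=False, float_format="%.10g")
    try:
        render_or_plot(results, cfg["null_interval_or"], out_dir / "or_plot.png")
        log["stages"]["plot"] = {"path": str(out_dir / "or_plot.png")}
    except Exception as exc:  # plotting must never kill a finished screen
        log["stages"]["plot"] = {"error": str(exc)}
    (out_dir / "run_log.json").write_text(json.dumps(_jsonable(log), indent=2))
    return results


def _literature_counts(cfg: dict, pmap, phecodes) -> LiteratureCounts:
    if cfg["provider"] == "fixture":
        fixture = cfg.get("literature_fixture", toy_data_path("toy_literature_counts.csv"))
        provider = FixtureProvider(fixture)
        return LiteratureCounts(
            disease_count=provider.disease_total(None),
            pair_counts={p: provider.pair_count(p, None, None) for p in phecodes},
        )
    # live provider: expand strings through the concept tables
    from .novelty import EntrezProvider

    icd9_cui, cui_strings = load_concept_tables(
        cfg.get("icd9_cui", toy_data_path("toy_icd9_cui.csv")),
        cfg.get("cui_strings", toy_data_path("toy_cui_strings.csv")),
    )
    provider = EntrezProvider(
        email=cfg.get("entrez_email", ""),
        api_key=cfg.get("entrez_api_key"),
        cache_path=cfg.get("pubmed_cache", "pubmed_cache.json"),
    )
    strings_by_phecode = {
        p: expand_concept_strings(p, pmap, icd9_cui, cui_strings).strings
        for p in phecodes
    }
    return fetch_counts(cfg["disease_strings"], strings_by_phecode, provider)


def render_or_plot(results: pd.DataFrame, null_or, path: str | Path):
    """Odds-ratio plot: one dot + CI segment per significant phecode.

    The null interval is drawn as a gray band; each finding is colored by its
    NFI over the [0, 10] scale and annotated with the NFI value.  With no
    significant findings the band is drawn with a notice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = results[(results["sgpv"] == 0.0) & results["nfi"].notna()]
    sig = sig.sort_values("or").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.45 * len(sig) + 1.5)))
    ax.axvspan(null_or[0], null_or[1], color="0.85", zorder=0,
               label=f"null interval [{null_or[0]}, {null_or[1]}]")
    if len(sig):
        cmap = plt.get_cmap("viridis")
        colors = [cmap(v / 10.0) for v in sig["nfi"]]
        y = np.arange(len(sig))
        for i, (_, row) in enumerate(sig.iterrows()):
            ax.plot([row["or_lo"], row["or_hi"]], [i, i], color=colors[i], lw=2)
            ax.annotate(f"{row['nfi']:.2f}", (row["or_hi"], i),
                        textcoords="offset points", xytext=(4, 2), fontsize=7)
        ax.scatter(sig["or"], y, c=colors, zorder=3)
        labels = [
            f"{r['phecode']} {r['label']}".strip() for _, r in sig.iterrows()
        ]
        ax.set_yticks(y, labels=labels, fontsize=7)
        ax.set_xscale("log")
    else:
        ax.text(0.5, 0.5, "no significant findings", transform=ax.transAxes,
                ha="center")
    ax.axvline(1.0, color="k", lw=0.5)
    ax.set_xlabel("odds ratio (log scale)")
    ax.set_title("Phenome-disease associations (color/annotation: NFI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, CensorWindow):
        return asdict(obj)
    if isinstance(obj, SimConfig):
        return str(obj)
    return obj
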