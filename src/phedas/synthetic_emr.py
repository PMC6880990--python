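"""Synthetic visit-level EMR cohorts with planted phecode-disease effects.

Real coded-record cohorts are private, so every pipeline stage is exercised
on generated data.  Carriage of each phecode is simulated directly from a
logistic model: controls carry phecode j with its background prevalence
``p0_j`` and cases with probability ``expit(logit(p0_j) + b_j)``, where
``b_j`` is the planted log odds ratio.  Carriers then receive ``1 +
Poisson(lambda)`` coded visits at ages consistent with the configured
censoring scenario, and each visit's phecode is "exploded" back into one of
its ICD-9 child codes so the mapping path is exercised, not bypassed.

Every draw flows from one ``numpy`` Generator seeded from the config, so the
same config and seed produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CensorWindow
from .errors import ConfigError
from .vocab import PhecodeMap, load_phecode_map, toy_data_path

__all__ = ["SimConfig", "simulate_cohort", "write_cohort", "end_to_end_recovery"]


@dataclass
class SimConfig:
    """Study conditions for a simulated case-control EMR extract.

    Defaults emulate the scale of a single-site retrospective phenome screen:
    1,000 subjects per arm, a catalog of modest-prevalence phecodes (5%
    background carriage), adult ages centred at 55 (sd 15, truncated to
    [0, 100]), a balanced sex ratio, and 1 + Poisson(2) coded visits per
    carried phecode.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    #: phecode -> background (control-arm) carriage prevalence
    prevalences: dict[str, float] = field(default_factory=dict)
    #: phecode -> planted log odds ratio (absent = 0, no effect)
    effects: dict[str, float] = field(default_factory=dict)
    age_mean: float = 55.0
    age_sd: float = 15.0
    female_frac: float = 0.5
    visit_lambda: float = 2.0
    #: visit ages scatter this many years around the subject's reference age
    visit_age_spread: float = 5.0
    window: CensorWindow = field(
        default_factory=lambda: CensorWindow("age_interval", 7.0, float("inf"))
    )
    seed: int = 0
    #: vocabulary used to explode phecodes into ICD-9 visit codes; phecodes
    #: without children in it get a same-named synthetic ICD-9 child
    phecode_map: PhecodeMap | None = None

    def __post_init__(self):
        problems = []
        if self.n_cases < 1 or self.n_controls < 1:
            problems.append("need at least one case and one control")
        if not self.prevalences:
            self.prevalences = {
                p: 0.05
                for p in ("296.2", "290.1", "345", "365", "288.6", "800", "807", "377.3")
            }
        for phe, prev in self.prevalences.items():
            if not 0.0 < prev < 1.0:
                problems.append(f"prevalence for {phe} must be in (0,1), got {prev}")
        for phe, b in self.effects.items():
            if phe not in self.prevalences:
                problems.append(f"planted effect on {phe} not in the phecode catalog")
            elif not np.isfinite(b):
                problems.append(f"non-finite planted log-OR for {phe}")
            else:
                p_case = expit(logit(self.prevalences[phe]) + b)
                if not 0.0 < p_case < 1.0:
                    problems.append(
                        f"implied case carriage probability for {phe} is degenerate"
                    )
        if not 0.0 <= self.female_frac <= 1.0:
            problems.append("female_frac must be in [0,1]")
        if problems:
            raise ConfigError("; ".join(problems))
        if self.phecode_map is None:
            self.phecode_map = load_phecode_map(toy_data_path("toy_phecode_map.csv"))

    @property
    def catalog(self) -> list[str]:
        return sorted(self.prevalences)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phecode": self.catalog,
                "true_log_or": [float(self.effects.get(p, 0.0)) for p in self.catalog],
            }
        )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _visit_age_window(config: SimConfig, ref_age: np.ndarray):
    """Per-subject [lo, hi) age range in which coded visits may fall."""
    w = config.window
    s = config.visit_age_spread
    if w.mode == "age_interval":
        lo = np.maximum(w.lo, ref_age - s)
        hi = np.minimum(w.hi, ref_age + s)
        hi = np.where(np.isfinite(hi), hi, ref_age + s)
    elif w.mode == "left_censor":
        lo, hi = ref_age - w.hi + 1e-9, ref_age - w.lo
    else:  # right_censor
        lo, hi = ref_age + w.lo, ref_age + w.hi - 1e-9
    lo = np.clip(lo, 0.0, 100.0)
    hi = np.clip(hi, lo + 1e-6, 100.0)
    return lo, hi


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (subjects, visits, truth) frames for one synthetic cohort.

    subjects: ``subject_id, sex, is_case, diagnosis_age`` (controls carry a
    reference age drawn from the same distribution, mirroring inheritance
    from a matched case).  visits: ``subject_id, age_at_visit, icd9``.
    truth: ``phecode, true_log_or`` for every catalog phecode.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    is_case = np.concatenate(
        [np.ones(config.n_cases, bool), np.zeros(config.n_controls, bool)]
    )
    ids = np.array([f"S{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_frac, "female", "male")
    ref_age = _truncated_normal(rng, config.age_mean, config.age_sd, 0.0, 100.0, n)

    catalog = config.catalog
    p0 = np.array([config.prevalences[p] for p in catalog])
    b = np.array([config.effects.get(p, 0.0) for p in catalog])
    p_subject = np.where(
        is_case[:, None], expit(logit(p0) + b)[None, :], p0[None, :]
    )
    carriage = rng.random((n, len(catalog))) < p_subject

    # explode carried phecodes into coded visits
    pmap = config.phecode_map
    children = {
        p: (pmap.children(p) or [p]) for p in catalog
    }
    subj_idx, phe_idx = np.nonzero(carriage)
    n_visits = 1 + rng.poisson(config.visit_lambda, subj_idx.size)
    rep_subj = np.repeat(subj_idx, n_visits)
    rep_phe = np.repeat(phe_idx, n_visits)
    lo, hi = _visit_age_window(config, ref_age)
    ages = rng.uniform(lo[rep_subj], hi[rep_subj])
    codes = np.empty(rep_phe.size, dtype=object)
    for j, phe in enumerate(catalog):
        mask = rep_phe == j
        kids = children[phe]
        codes[mask] = np.asarray(kids, dtype=object)[
            rng.integers(0, len(kids), int(mask.sum()))
        ]

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "sex": sex,
            "is_case": is_case.astype(int),
            "diagnosis_age": np.round(ref_age, 3),
        }
    )
    visits = pd.DataFrame(
        {
            "subject_id": ids[rep_subj],
            "age_at_visit": np.round(ages, 3),
            "icd9": codes,
        }
    ).sort_values(["subject_id", "age_at_visit", "icd9"], kind="mergesort")
    return subjects, visits.reset_index(drop=True), config.truth_table()


def write_cohort(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the CSV files the loaders consume.

    Emits ``subjects.csv``, ``visits.csv``, ``truth.csv`` and a
    ``phecode_map.csv`` covering the catalog (synthetic same-named ICD-9
    children are added for phecodes without children in the vocabulary).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, visits, truth = simulate_cohort(config)
    paths = {
        "subjects": out_dir / "subjects.csv",
        "visits": out_dir / "visits.csv",
        "truth": out_dir / "truth.csv",
        "phecode_map": out_dir / "phecode_map.csv",
    }
    subjects.to_csv(paths["subjects"], index=False)
    visits.to_csv(paths["visits"], index=False)
    truth.to_csv(paths["truth"], index=False)

    pmap = config.phecode_map
    cover = PhecodeMap()
    for phe in config.catalog:
        kids = pmap.children(phe) or [phe]
        for k in kids:
            cover.code_to_phecode[k] = phe
        cover.labels[phe] = pmap.labels.get(phe, f"synthetic phecode {phe}")
        if phe in pmap.exclude_ranges:
            cover.exclude_ranges[phe] = pmap.exclude_ranges[phe]
    cover.to_csv(paths["phecode_map"])
    return paths


def end_to_end_recovery(
    config: SimConfig,
    null_interval_or=(0.3, 1.5),
    pi0: float = 0.5,
    level: float = 0.95,
    min_carriers: int = 5,
) -> pd.DataFrame:
    """Run the full pipeline on one simulated cohort and audit recovery.

    Returns a per-phecode report joining the screen's estimates, SGPV and PPV
    with the planted truth: ``detected`` marks p_delta = 0 calls,
    ``truly_alternative`` marks phecodes whose planted log-OR lies outside
    the null interval, and ``correct`` whether the call matches the truth.
    """
    from .screen import PhecodeScreen
    from .sgpv import NullInterval, SgpvRanker
    from .vocab import map_visits

    subjects, visits, truth = simulate_cohort(config)
    mapped, _ = map_visits(visits, config.phecode_map)
    from .cohort import aggregate, censor_visits

    censored = censor_visits(mapped, subjects, config.window)
    matrix = aggregate(
        censored, subjects, measure="binary", phecodes=config.catalog
    )
    screen = PhecodeScreen(level=level, min_carriers=min_carriers).fit(matrix)
    ranked = SgpvRanker(null_or=null_interval_or, pi0=pi0, level=level).transform(
        screen.results_
    )
    null = NullInterval.from_or(*null_interval_or)
    report = ranked.merge(truth, on="phecode", how="right")
    report["detected"] = report["sgpv"] == 0.0
    report["truly_alternative"] = ~report["true_log_or"].between(null.lo, null.hi)
    report["correct"] = report["detected"] == report["truly_alternative"]
    return report
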