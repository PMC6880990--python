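"""Literature novelty: PubMed proportions, novelty scores, and the NFI.

For an index disease and each phecode paired with it, a provider counts the
papers whose title/abstract/keywords mention both the disease's strings and
the phecode's strings.  The PubMed proportion is the pair count divided by
the disease count.  Ranking those proportions through their empirical CDF
gives the novelty score

    n_s = 1 - Fhat(x),   Fhat(x) = #{proportions <= x} / M

so the most-studied pairing scores exactly 0 and understudied pairings score
near 1.  The Novelty Finding Index combines reliability and novelty:

    NFI = (PPV * n_s) * 10  in [0, 10]

(the factor 10 keeps the index from being misread as a probability).  NFI is
reported only for findings with p_delta = 0, where the PPV is defined.

Two providers are available: a versioned fixture file (default; pins counts
so results stay reproducible while the live literature grows) and a live
NCBI E-utilities client with on-disk caching and rate limiting.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "LiteratureCounts",
    "build_query",
    "FixtureProvider",
    "EntrezProvider",
    "fetch_counts",
    "novelty_score",
    "nfi",
    "NoveltyIndex",
]


@dataclass
class LiteratureCounts:
    """Paper counts for one index disease and its phecode pairings."""

    disease_count: int
    pair_counts: dict[str, int] = field(default_factory=dict)

    def proportions(self) -> dict[str, float]:
        """PubMed proportion per phecode: pair_count / disease_count."""
        if self.disease_count <= 0:
            return {k: 0.0 for k in self.pair_counts}
        return {k: v / self.disease_count for k, v in self.pair_counts.items()}


def build_query(strings_a: Iterable[str], strings_b: Iterable[str] | None = None) -> str:
    """Normalized fielded query: (any of A) [AND (any of B)].

    Terms are lowercased, deduplicated and sorted so equivalent string sets
    hash to the same cache key; each term is fielded to title/abstract
    (``[tiab]``, which in PubMed also covers author keywords).
    """
    def _block(strings):
        terms = sorted({s.strip().lower() for s in strings if s and s.strip()})
        if not terms:
            raise ValueError("empty search string set")
        return "(" + " OR ".join(f'"{t}"[tiab]' for t in terms) + ")"

    q = _block(strings_a)
    if strings_b is not None:
        q += " AND " + _block(strings_b)
    return q


class FixtureProvider:
    """Counts from a pinned local file; never touches the network.

    File format: an optional leading comment line ``# disease_count: <int>``
    followed by CSV with header ``phecode,pair_count``.  Phecodes absent from
    the file count 0 (with a warning at lookup time).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.disease_count = 0
        self._pairs: dict[str, int] = {}
        with open(self.path) as fh:
            first = fh.readline()
            if first.lstrip().startswith("#"):
                self.disease_count = int(first.split(":", 1)[1].strip())
                header = fh.readline()
            else:
                header = first
            cols = [c.strip() for c in header.strip().split(",")]
            if cols[:2] != ["phecode", "pair_count"]:
                raise ValueError(
                    f"{self.path}: expected header 'phecode,pair_count', got {header!r}"
                )
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                phe, cnt = line.split(",")[:2]
                self._pairs[phe.strip()] = int(cnt)

    def disease_total(self, disease_strings) -> int:
        return self.disease_count

    def pair_count(self, phecode: str, disease_strings, phecode_strings) -> int:
        if phecode not in self._pairs:
            warnings.warn(
                f"fixture {self.path} has no counts for phecode {phecode}; using 0",
                stacklevel=2,
            )
            return 0
        return self._pairs[phecode]


class EntrezProvider:
    """Live PubMed counts via NCBI E-utilities esearch, cached to disk.

    Counts are fetched with ``rettype=count``-style esearch calls (retmax=0),
    at most ``max_rate`` requests per second, with ``retries`` attempts before
    a hard error naming the failing query.  Responses are cached in a JSON
    file keyed by the sha1 of the normalized query, so a warm cache issues no
    network requests at all.

    ``fetch`` is an injectable callable ``query -> count`` used for testing
    with recorded responses; by default it calls Bio.Entrez.
    """

    def __init__(
        self,
        email: str,
        api_key: str | None = None,
        cache_path: str | Path = "pubmed_cache.json",
        max_rate: float = 3.0,
        retries: int = 3,
        fetch: Callable[[str], int] | None = None,
    ):
        self.email = email
        self.api_key = api_key
        self.cache_path = Path(cache_path)
        self.min_interval = 1.0 / max_rate
        self.retries = retries
        self._fetch = fetch or self._entrez_count
        self._last_request = 0.0
        self._cache: dict[str, dict] = {}
        if self.cache_path.exists():
            self._cache = json.loads(self.cache_path.read_text())
        self.n_requests = 0

    def _entrez_count(self, query: str) -> int:  # pragma: no cover - network
        from Bio import Entrez

        Entrez.email = self.email
        if self.api_key:
            Entrez.api_key = self.api_key
        handle = Entrez.esearch(db="pubmed", term=query, retmax=0)
        record = Entrez.read(handle)
        handle.close()
        return int(record["Count"])

    def count(self, query: str) -> int:
        key = hashlib.sha1(query.encode()).hexdigest()
        if key in self._cache:
            return int(self._cache[key]["count"])
        err: Exception | None = None
        for _ in range(self.retries):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                n = self._fetch(query)
                self.n_requests += 1
                break
            except Exception as exc:  # noqa: BLE001 - retried, then re-raised
                err = exc
        else:
            raise RuntimeError(f"PubMed query failed after retries: {query!r}") from err
        self._cache[key] = {"count": n, "query": query, "timestamp": time.time()}
        self.cache_path.write_text(json.dumps(self._cache, indent=0))
        return n

    def disease_total(self, disease_strings) -> int:
        return self.count(build_query(disease_strings))

    def pair_count(self, phecode: str, disease_strings, phecode_strings) -> int:
        return self.count(build_query(disease_strings, phecode_strings))


def fetch_counts(
    disease_strings: Iterable[str],
    phecode_strings_by_phecode: Mapping[str, Iterable[str]],
    provider,
) -> LiteratureCounts:
    """Collect literature counts for a disease and its phecode pairings."""
    disease_strings = list(disease_strings)
    if not disease_strings:
        raise ValueError("disease_strings must be non-empty")
    total = int(provider.disease_total(disease_strings))
    pairs = {}
    for phe, strings in phecode_strings_by_phecode.items():
        strings = list(strings)
        if not strings:
            warnings.warn(f"phecode {phe}: no search strings; count 0", stacklevel=2)
            pairs[phe] = 0
            continue
        pairs[phe] = int(provider.pair_count(phe, disease_strings, strings))
    return LiteratureCounts(disease_count=total, pair_counts=pairs)


def novelty_score(proportions) -> np.ndarray | dict[str, float]:
    """Novelty score 1 - Fhat(x) over the proportions under consideration.

    Fhat is the right-continuous, self-inclusive empirical CDF, so the
    maximum proportion always scores exactly 0 and ties share a value.
    Accepts an array-like (returns ndarray) or a dict keyed by phecode
    (returns a dict with the same keys).
    """
    if isinstance(proportions, Mapping):
        keys = list(proportions.keys())
        vals = np.asarray([proportions[k] for k in keys], dtype=float)
        scores = novelty_score(vals)
        return dict(zip(keys, scores.tolist()))
    x = np.asarray(list(proportions), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one proportion")
    ecdf = (x[None, :] <= x[:, None]).mean(axis=1)
    return 1.0 - ecdf


def nfi(ppv: float, n_s: float) -> float:
    """Novelty Finding Index: (PPV * n_s) * 10, in [0, 10]."""
    if not (0.0 <= ppv <= 1.0 and 0.0 <= n_s <= 1.0):
        raise ValueError("ppv and n_s must both lie in [0, 1]")
    return ppv * n_s * 10.0


class NoveltyIndex:
    """Transformer adding PubMed proportion, novelty score and NFI columns.

    Expects the table produced by :class:`phedas.sgpv.SgpvRanker` (columns
    ``phecode``, ``sgpv``, ``ppv``) plus a LiteratureCounts object.

    Parameters
    ----------
    counts : LiteratureCounts
    restrict_to_significant : bool, default False
        When True the ECDF behind the novelty score is estimated only from
        the p_delta = 0 findings; by default it uses every screened phecode,
        which stabilizes the reference distribution.
    """

    def __init__(self, counts: LiteratureCounts, restrict_to_significant: bool = False):
        self.counts = counts
        self.restrict_to_significant = restrict_to_significant

    def get_params(self, deep=True):
        return {
            "counts": self.counts,
            "restrict_to_significant": self.restrict_to_significant,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, results):
        import pandas as pd

        out = results.copy()
        props = self.counts.proportions()
        out["pubmed_proportion"] = out["phecode"].map(props)
        missing = out["pubmed_proportion"].isna()
        if missing.any():
            warnings.warn(
                f"no literature counts for {int(missing.sum())} phecodes; "
                "treating their proportions as 0",
                stacklevel=2,
            )
            out.loc[missing, "pubmed_proportion"] = 0.0

        if self.restrict_to_significant:
            ref_mask = out["sgpv"] == 0.0
        else:
            ref_mask = pd.Series(True, index=out.index)
        out["n_s"] = np.nan
        if ref_mask.any():
            ref = out.loc[ref_mask, "pubmed_proportion"].to_numpy()
            # score each row against the reference set's ECDF
            scored = out.loc[ref_mask].index
            ecdf_scores = novelty_score(ref)
            out.loc[scored, "n_s"] = ecdf_scores
        out["nfi"] = np.where(
            (out["sgpv"] == 0.0) & out["ppv"].notna() & out["n_s"].notna(),
            out["ppv"] * out["n_s"] * 10.0,
            np.nan,
        )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
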