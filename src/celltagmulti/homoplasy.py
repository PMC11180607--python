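"""Simulation of CellTag delivery to estimate the expected rate of homoplasy.

Homoplasy: two founder cells independently drawing identical CellTag
signatures, which downstream clone calling cannot distinguish from shared
descent. The simulator models one tagging experiment: each of ``n_cells``
founders receives ``k ~ Poisson(moi)`` barcodes, rejection-resampled into
``tag_range`` (a cell needs at least one tag to be observed, and more than
~25 integrations is biologically implausible), drawn without replacement
from the viral library (uniform over ``library_size`` barcodes, or weighted
by allowlist abundance). The homoplasy rate is the fraction of cells whose
exact signature set-equals another cell's; averaging over 100 independent
simulations gives the expected rate.

``moi`` is the mean of the *untruncated* Poisson; rejection into
``tag_range`` makes the realized mean tags/cell slightly higher (e.g. 3.52
at moi 3.4 on [1, 25]).

Reference configurations: the in vitro hematopoiesis experiment used 5,500
founders at MOI 3.4 with a ~25,000-barcode virus aliquot; the fibroblast
reprogramming experiment used 30,000 founders at MOI 2.25 with the full
~80,000-barcode library and excluded ambiguous single-tag signatures before
scoring, mirroring its clone-calling filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .allowlist import Allowlist


@dataclass(frozen=True)
class HomoplasySimParams:
    """Parameters of one simulated tagging experiment.

    ``library`` is either an integer library size (uniform barcode
    abundance) or an :class:`~celltagmulti.allowlist.Allowlist` whose
    weights, if present, bias the draw.
    """

    n_cells: int
    moi: float
    tag_range: tuple[int, int] = (1, 25)
    library: int | Allowlist = 25_000
    n_sims: int = 100
    seed: int = 0
    exclude_ambiguous_singletons: bool = False
    #: divide duplicated-cell counts by the full simulated population rather
    #: than by the cells remaining after singleton exclusion
    score_relative_to_population: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        lo, hi = self.tag_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid tag_range {self.tag_range}")
        if hi > self.library_size:
            raise ValueError(
                f"tag_range upper bound {hi} exceeds library size {self.library_size}"
            )

    @property
    def library_size(self) -> int:
        return self.library if isinstance(self.library, int) else len(self.library)

    @property
    def weights(self) -> np.ndarray | None:
        if isinstance(self.library, Allowlist) and self.library.abundance is not None:
            w = self.library.abundance
            return w / w.sum()
        return None


@dataclass
class HomoplasyResult:
    """Mean homoplasy rate with per-simulation rates and realized tag counts."""

    mean_rate: float
    per_sim_rates: np.ndarray
    realized_mean_tags: float
    params: HomoplasySimParams = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mean_rate": self.mean_rate,
            "per_sim_rates": self.per_sim_rates.tolist(),
            "realized_mean_tags": self.realized_mean_tags,
            "n_sims": len(self.per_sim_rates),
        }


def _draw_tag_counts(params: HomoplasySimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-cell integration counts: Poisson(moi) rejected into tag_range."""
    lo, hi = params.tag_range
    k = rng.poisson(params.moi, params.n_cells)
    bad = (k < lo) | (k > hi)
    while bad.any():
        k[bad] = rng.poisson(params.moi, int(bad.sum()))
        bad = (k < lo) | (k > hi)
    return k


def _draw_signatures(
    k: np.ndarray, params: HomoplasySimParams, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Draw k[i] distinct library barcodes per cell, as sorted index tuples.

    Uniform draws use with-replacement sampling plus per-cell rejection of
    duplicates (duplicates are rare for k << sqrt(library size), so this is
    much faster than per-cell ``choice(replace=False)``); weighted draws use
    inverse-CDF sampling with the same rejection.
    """
    L = params.library_size
    weights = params.weights
    cdf = None if weights is None else np.cumsum(weights)

    def draw(total: int) -> np.ndarray:
        if cdf is None:
            return rng.integers(0, L, total)
        return np.searchsorted(cdf, rng.random(total), side="right").astype(np.int64)

    offsets = np.concatenate([[0], np.cumsum(k)])
    flat = draw(int(offsets[-1]))
    sigs: list[tuple[int, ...]] = []
    for i in range(len(k)):
        cell = flat[offsets[i] : offsets[i + 1]]
        tags = np.unique(cell)
        while len(tags) < k[i]:
            cell = draw(int(k[i]))
            tags = np.unique(cell)
        sigs.append(tuple(tags.tolist()))
    return sigs


def simulate_tagging_once(
    params: HomoplasySimParams, rng: np.random.Generator
) -> tuple[list[tuple[int, ...]], float]:
    """One simulated tagging experiment: (signatures, homoplasy rate).

    With ``exclude_ambiguous_singletons`` the single-tag cells whose tag
    also occurs in a multi-tag signature are removed before scoring (the
    same rule clone calling applies to real data). The rate is the number
    of scored cells whose signature set-equals another scored cell's,
    divided by the number of scored cells.
    """
    k = _draw_tag_counts(params, rng)
    sigs = _draw_signatures(k, params, rng)
    scored = sigs
    if params.exclude_ambiguous_singletons:
        multi_tags: set[int] = set()
        for s in sigs:
            if len(s) > 1:
                multi_tags.update(s)
        scored = [s for s in sigs if not (len(s) == 1 and s[0] in multi_tags)]
    counts = Counter(scored)
    n_dup = sum(c for c in counts.values() if c > 1)
    denom = params.n_cells if params.score_relative_to_population else len(scored)
    rate = n_dup / denom if denom else 0.0
    return sigs, rate


def expected_homoplasy(params: HomoplasySimParams) -> HomoplasyResult:
    """Mean homoplasy rate over ``params.n_sims`` independent simulations.

    Deterministic given ``params`` (including ``seed``); per-simulation
    rates are returned for uncertainty estimates.
    """
    rng = np.random.default_rng(params.seed)
    rates = np.empty(params.n_sims)
    tag_totals = 0.0
    for s in range(params.n_sims):
        sigs, rates[s] = simulate_tagging_once(params, rng)
        tag_totals += sum(len(x) for x in sigs)
    return HomoplasyResult(
        mean_rate=float(rates.mean()),
        per_sim_rates=rates,
        realized_mean_tags=tag_totals / (params.n_sims * params.n_cells),
        params=params,
    )


#: Published experiment configurations (seed left at the dataclass default).
HEMATOPOIESIS_CONFIG = HomoplasySimParams(
    n_cells=5_500, moi=3.4, tag_range=(1, 25), library=25_000, n_sims=100
)
REPROGRAMMING_CONFIG = HomoplasySimParams(
    n_cells=30_000,
    moi=2.25,
    tag_range=(1, 25),
    library=80_000,
    n_sims=100,
    exclude_ambiguous_singletons=True,
)


def with_seed(params: HomoplasySimParams, seed: int) -> HomoplasySimParams:
    """Copy of ``params`` with a new seed."""
    return replace(params, seed=seed)
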