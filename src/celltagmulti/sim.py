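"""Synthetic CellTag experiments with known ground truth.

Generates everything the pipeline consumes — an allowlisted barcode
library, clonal populations with truncated-Poisson tag sets, raw reads per
(time point, modality) with UMIs, dropout and per-base sequencing errors,
fate-linked feature matrices and cell metadata — so extraction, clone
calling and state–fate analysis can be exercised end to end without any
download, and recovered results can be scored against the planted truth.

Default parameters mirror the in vitro hematopoiesis experiment: founders
tagged at MOI 3.4 from a 25,000-barcode library (1–25 tags/cell), cells
split evenly across two time points and two modalities, geometric clone
sizes (heavy right tail, as seen for expanding myeloid clones). Dropout
acts at the captured-cell level (each founder tag is lost independently
with ``dropout_rate``), modeling modality capture differences; sequencing
error is an iid per-base substitution. What the generator does **not**
model: clonal selection between tagging and sampling, barcode silencing,
ambient contamination, or realistic count distributions (features are
Gaussian shifts keyed to the clone's fate).

The fate/feature model assigns each clone a fate label; cells adhere to it
with probability ``fate_adherence`` (otherwise a random other fate). State
cells' features are the fate's effect vector (a disjoint feature block per
fate, shifted by ``effect_size`` standard deviations) plus unit Gaussian
noise. With ``signal_mode="half"`` the RNA block encodes only one half of
the fate identity and the ATAC block the other half, so each modality alone
carries half of the discriminative information and only their combination
identifies the fate — the scenario where multi-omic state capture should
outperform either single modality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .allowlist import Allowlist
from .clones import CLONE_TABLE_COLUMNS, CloneTable
from .homoplasy import HomoplasySimParams, _draw_signatures, _draw_tag_counts
from .patterns import BUILTIN_PATTERNS, BarcodePattern, reverse_complement
from .reads import ATAC, RNA, TaggedRead

_BASES = np.array(list("ACGT"))


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """n unique random nucleotide sequences of the given length."""
    out: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        out.update("".join(_BASES[row]) for row in block)
    return sorted(out)


def make_allowlist(
    n: int, length: int = 18, seed: int = 0, skewed: bool = False
) -> Allowlist:
    """A synthetic allowlist; ``skewed`` adds log-normal abundance weights."""
    rng = np.random.default_rng(seed)
    barcodes = random_barcodes(n, length, rng)
    abundance = rng.lognormal(0, 1, n) if skewed else None
    return Allowlist(barcodes=barcodes, abundance=abundance)


@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Parameters of a simulated CellTag-multi experiment."""

    n_clones: int = 200
    clone_size_mean: float = 5.0
    library_size: int = 25_000
    moi: float = 3.4
    tag_range: tuple[int, int] = (1, 25)
    #: capture fractions per (time_point, modality); must sum to 1
    splits: tuple[tuple[tuple[str, str], float], ...] = (
        (("d2.5", RNA), 0.25),
        (("d2.5", ATAC), 0.25),
        (("d5", RNA), 0.25),
        (("d5", ATAC), 0.25),
    )
    state_timepoint: str = "d2.5"
    fate_timepoint: str = "d5"
    dropout_rate: float = 0.1
    error_rate: float = 0.005
    umis_per_tag: int = 3
    reads_per_umi: int = 2
    reads_per_tag_atac: int = 3
    fates: tuple[str, ...] = ("Mono", "Neu")
    fate_adherence: float = 0.9
    n_features: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    signal_mode: str = "full"  # full | half | none
    flank: int = 5
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.splits)
        if not np.isclose(total, 1.0):
            raise ValueError(f"split fractions sum to {total}, not 1")
        for rate in (self.dropout_rate, self.error_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.dropout_rate >= 1:
            raise ValueError("dropout rate 1 leaves empty signatures")
        if self.signal_mode not in ("full", "half", "none"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


#: Four composite fates for the half-signal (multi-omic gain) scenario.
HALF_SIGNAL_FATES = ("EryA", "EryB", "MyeA", "MyeB")


def half_signal_spec(**overrides) -> SyntheticExperimentSpec:
    """Spec preset where RNA and ATAC each resolve half of the fate identity.

    Fates are the four combinations of a lineage axis (Ery/Mye; encoded in
    the RNA features) and a sublineage axis (A/B; encoded in ATAC
    features).
    """
    defaults = dict(fates=HALF_SIGNAL_FATES, signal_mode="half")
    defaults.update(overrides)
    return SyntheticExperimentSpec(**defaults)


@dataclass
class SyntheticExperiment:
    """Ground truth plus every raw artifact of one simulated experiment."""

    spec: SyntheticExperimentSpec
    truth: CloneTable
    reads: dict[tuple[str, str], list[TaggedRead]]
    features: dict[str, pd.DataFrame]
    cell_types: pd.Series
    metadata: pd.DataFrame
    allowlist: Allowlist
    pattern: BarcodePattern
    founder_signatures: dict[int, frozenset[str]] = field(default_factory=dict)

    def all_reads(self) -> list[TaggedRead]:
        return list(itertools.chain.from_iterable(self.reads.values()))


def _fate_effect(
    spec: SyntheticExperimentSpec, fate: str, modality: str
) -> np.ndarray:
    """Mean feature vector of a fate in one modality's feature space."""
    effect = np.zeros(spec.n_features)
    if spec.signal_mode == "none" or spec.effect_size == 0:
        return effect
    if spec.signal_mode == "half":
        # RNA sees the first half of the fate name, ATAC the second half
        groups = sorted({f[:3] for f in spec.fates}) if modality == RNA else sorted(
            {f[3:] for f in spec.fates}
        )
        key = fate[:3] if modality == RNA else fate[3:]
        idx = groups.index(key)
        n_groups = len(groups)
    else:
        idx = spec.fates.index(fate)
        n_groups = len(spec.fates)
    block = max(1, spec.n_features // n_groups)
    effect[idx * block : (idx + 1) * block] = spec.effect_size
    return effect


def _sequence_with_errors(
    barcode: str,
    pattern: BarcodePattern,
    spec: SyntheticExperimentSpec,
    rng: np.random.Generator,
) -> str:
    seq = list(
        "".join(_BASES[rng.integers(0, 4, spec.flank)])
        + pattern.embed(barcode)
        + "".join(_BASES[rng.integers(0, 4, spec.flank)])
    )
    if spec.error_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < spec.error_rate)
        for i in hits:
            seq[i] = _BASES[(("ACGT".index(seq[i])) + rng.integers(1, 4)) % 4]
    return "".join(seq)


def simulate_experiment(spec: SyntheticExperimentSpec) -> SyntheticExperiment:
    """Run one synthetic experiment; deterministic given ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    pattern = BUILTIN_PATTERNS["v1"]
    allowlist = make_allowlist(spec.library_size, pattern.random_length, seed=spec.seed)

    # founders: tag sets exactly as in the homoplasy simulator
    hp = HomoplasySimParams(
        n_cells=max(spec.n_clones, 2),
        moi=spec.moi,
        tag_range=spec.tag_range,
        library=spec.library_size,
    )
    k = _draw_tag_counts(hp, rng)
    founder_idx = _draw_signatures(k, hp, rng)
    founder_sigs = {
        c: frozenset(allowlist.barcodes[i] for i in idx)
        for c, idx in enumerate(founder_idx)
    }

    # clone fates and sizes
    fate_of_clone = {
        c: spec.fates[rng.integers(0, len(spec.fates))] for c in range(spec.n_clones)
    }
    # geometric on {1, 2, ...} with the requested mean
    sizes = rng.geometric(1.0 / max(spec.clone_size_mean, 1.0), spec.n_clones)

    split_keys = [key for key, _ in spec.splits]
    split_probs = np.array([f for _, f in spec.splits])

    rows = []  # truth clone table rows
    reads: dict[tuple[str, str], list[TaggedRead]] = {key: [] for key in split_keys}
    feature_rows: dict[str, dict[str, np.ndarray]] = {RNA: {}, ATAC: {}}
    cell_types: dict[str, str] = {}
    n_cell = 0
    for c in range(spec.n_clones):
        captures = rng.choice(len(split_keys), size=sizes[c], p=split_probs)
        fate = fate_of_clone[c]
        for cap in captures:
            time_point, modality = split_keys[cap]
            cell = f"cell{n_cell:06d}"
            n_cell += 1
            # realized cell type: adhere to the clone fate or defect
            if rng.random() < spec.fate_adherence or len(spec.fates) == 1:
                cell_fate = fate
            else:
                others = [f for f in spec.fates if f != fate]
                cell_fate = others[rng.integers(0, len(others))]
            cell_types[cell] = cell_fate
            rows.append((c, cell, modality, time_point, spec.sample_id, fate))

            # captured signature: founder tags after per-tag dropout
            sig = [
                t for t in sorted(founder_sigs[c]) if rng.random() >= spec.dropout_rate
            ]
            for tag in sig:
                if modality == RNA:
                    for _ in range(spec.umis_per_tag):
                        umi = "".join(_BASES[rng.integers(0, 4, 10)])
                        for _ in range(spec.reads_per_umi):
                            seq = _sequence_with_errors(tag, pattern, spec, rng)
                            reads[(time_point, modality)].append(
                                TaggedRead(cell, umi, seq, RNA, spec.sample_id)
                            )
                else:
                    for _ in range(spec.reads_per_tag_atac):
                        seq = _sequence_with_errors(tag, pattern, spec, rng)
                        if rng.random() < 0.5:
                            seq = reverse_complement(seq)
                        reads[(time_point, modality)].append(
                            TaggedRead(cell, None, seq, ATAC, spec.sample_id)
                        )

            # state-cell features keyed to the clone fate
            if time_point == spec.state_timepoint:
                effect = _fate_effect(spec, fate, modality)
                feature_rows[modality][cell] = effect + rng.normal(
                    0, spec.noise_sd, spec.n_features
                )

    truth_df = pd.DataFrame(
        rows, columns=["clone_id", "cell", "modality", "time_point", "sample", "fate_label"]
    )
    # realized fate bias among fate-time-point siblings
    fate_cells = truth_df[truth_df["time_point"] == spec.fate_timepoint]
    bias = {}
    for cid, grp in fate_cells.groupby("clone_id"):
        agree = [cell_types[c] == fate_of_clone[cid] for c in grp["cell"]]
        bias[cid] = float(np.mean(agree))
    truth_df["fate_bias"] = truth_df["clone_id"].map(bias)
    truth_df["tie_flag"] = False
    truth = CloneTable(truth_df[CLONE_TABLE_COLUMNS])

    features = {
        mod: pd.DataFrame.from_dict(
            rows_, orient="index", columns=[f"{mod.lower()}_f{j}" for j in range(spec.n_features)]
        ).sort_index()
        for mod, rows_ in feature_rows.items()
        if rows_
    }
    metadata = truth_df[["cell", "modality", "time_point", "sample", "clone_id"]].copy()
    metadata["cell_type"] = metadata["cell"].map(cell_types)
    return SyntheticExperiment(
        spec=spec,
        truth=truth,
        reads=reads,
        features=features,
        cell_types=pd.Series(cell_types, name="cell_type"),
        metadata=metadata.set_index("cell"),
        allowlist=allowlist,
        pattern=pattern,
        founder_signatures=founder_sigs,
    )


def inject_crosstalk(
    reads_a: list[TaggedRead],
    reads_b: list[TaggedRead],
    rate: float,
    seed: int = 0,
) -> tuple[list[TaggedRead], list[TaggedRead], pd.DataFrame]:
    """Reassign a fraction of each stream's reads to cells of the other stream.

    Emulates barcode leakage between two co-processed libraries (the
    species-mixing design): each read keeps its library identity but, with
    probability ``rate``, lands in a random cell of the other stream.
    Returns the two mixed streams plus a per-cell ground-truth table of
    (expected-library reads, other-library reads).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells_a = sorted({r.cell_barcode for r in reads_a})
    cells_b = sorted({r.cell_barcode for r in reads_b})

    def mix(stream: list[TaggedRead], other_cells: list[str]) -> list[TaggedRead]:
        out = []
        for r in stream:
            if other_cells and rng.random() < rate:
                target = other_cells[rng.integers(0, len(other_cells))]
                out.append(replace(r, cell_barcode=target))
            else:
                out.append(r)
        return out

    mixed_a = mix(reads_a, cells_b)
    mixed_b = mix(reads_b, cells_a)
    tally: dict[tuple[str, str], list[int]] = {}
    for cell in cells_a:
        tally[(cell, "A")] = [0, 0]
    for cell in cells_b:
        tally[(cell, "B")] = [0, 0]
    for library, stream in (("A", mixed_a), ("B", mixed_b)):
        for r in stream:
            for species in ("A", "B"):
                key = (r.cell_barcode, species)
                if key in tally:
                    tally[key][0 if species == library else 1] += 1
    rows = [
        (cell, species, own, foreign)
        for (cell, species), (own, foreign) in sorted(tally.items())
    ]
    truth = pd.DataFrame(
        rows, columns=["cell", "species", "expected_library_reads", "other_library_reads"]
    )
    return mixed_a, mixed_b, truth


def knn_graph(features: pd.DataFrame, k: int = 10) -> nx.Graph:
    """Cell-cell kNN graph over a feature frame; edge weight = 1/(1+distance)."""
    from sklearn.neighbors import NearestNeighbors

    X = features.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(features))).fit(X)
    dist, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(features.index)
    names = list(features.index)
    for i, row in enumerate(idx):
        for j, d in zip(row[1:], dist[i][1:]):
            g.add_edge(names[i], names[j], weight=1.0 / (1.0 + float(d)))
    return g
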