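"""Clone calling from binary CellTag signatures and clone-level annotation.

Cells sharing a lentiviral CellTag signature descend from one tagged
founder. Clones are recovered by thresholding the cell-cell Jaccard
similarity of signatures — 0.6 within a modality, 0.5 across RNA/ATAC by
default (cross-modality capture differs, so a slightly looser threshold is
used) — and taking connected components of the resulting graph. Components
are the minimal reading of "identify clones from the thresholded matrix"
and are invariant to cell order.

Clone annotation then assigns each clone a fate label (the modal cell type
among its fate-time-point siblings, optionally after grouping scarce
lineages such as Ery/Meg) and a fate bias (fraction of fate siblings in the
modal group).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .matrix import BinarySignatureSet

CLONE_TABLE_COLUMNS = [
    "clone_id",
    "cell",
    "modality",
    "time_point",
    "sample",
    "fate_label",
    "fate_bias",
    "tie_flag",
]


@dataclass(frozen=True)
class CloneCallParams:
    """Jaccard thresholds for clone calling.

    ``tau_intra`` applies to same-modality cell pairs, ``tau_cross`` to
    RNA-vs-ATAC pairs. Thresholds are inclusive (edge kept when J >= tau)
    unless ``inclusive`` is unset.
    """

    tau_intra: float = 0.6
    tau_cross: float = 0.5
    inclusive: bool = True

    def __post_init__(self) -> None:
        for tau in (self.tau_intra, self.tau_cross):
            if not 0 < tau <= 1:
                raise ValueError(f"threshold {tau} outside (0, 1]")


#: Reprogramming-style configuration: one uniform threshold for all pairs.
REPROGRAMMING_PARAMS = CloneCallParams(tau_intra=0.6, tau_cross=0.6)


class CloneTable:
    """A partition of cells into clones, as a tidy cell-level DataFrame.

    Clone ids are deterministic: clones are numbered by descending size,
    ties by lexicographically smallest member cell.
    """

    def __init__(self, cells: pd.DataFrame):
        missing = set(CLONE_TABLE_COLUMNS) - set(cells.columns)
        if missing:
            raise ValueError(f"clone table missing columns {sorted(missing)}")
        if cells["cell"].duplicated().any():
            dupes = cells.loc[cells["cell"].duplicated(), "cell"].tolist()
            raise ValueError(f"cells assigned to multiple clones: {dupes[:5]}")
        self.cells = cells.reset_index(drop=True)

    def __len__(self) -> int:
        return int(self.cells["clone_id"].nunique())

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def members(self, clone_id: int) -> list[str]:
        return self.cells.loc[self.cells["clone_id"] == clone_id, "cell"].tolist()

    def sizes(self) -> pd.Series:
        return self.cells.groupby("clone_id").size().sort_index()

    def partition(self) -> dict[str, int]:
        """cell -> clone_id map."""
        return dict(zip(self.cells["cell"], self.cells["clone_id"]))

    def clone_summary(self) -> pd.DataFrame:
        """One row per clone: size, fate label/bias, tie flag."""
        g = self.cells.groupby("clone_id")
        return pd.DataFrame(
            {
                "size": g.size(),
                "fate_label": g["fate_label"].first(),
                "fate_bias": g["fate_bias"].first(),
                "tie_flag": g["tie_flag"].first(),
            }
        ).sort_index()

    def state_fate_clones(
        self, state_timepoints: Iterable[str], fate_timepoints: Iterable[str]
    ) -> list[int]:
        """Clones with >=1 sibling at a state time point and >=1 at a fate one."""
        state_tp, fate_tp = set(state_timepoints), set(fate_timepoints)
        out = []
        for cid, grp in self.cells.groupby("clone_id"):
            tps = set(grp["time_point"])
            if tps & state_tp and tps & fate_tp:
                out.append(cid)
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CloneTable":
        df = pd.read_csv(path, sep="\t", dtype={"cell": str})
        return cls(df)


def jaccard(s1: frozenset | set, s2: frozenset | set) -> float:
    """Jaccard similarity |s1 & s2| / |s1 | s2| of two nonempty tag sets."""
    if not s1 or not s2:
        raise ValueError("Jaccard of an empty signature is undefined")
    inter = len(s1 & s2)
    return inter / (len(s1) + len(s2) - inter)


def call_clones(
    signatures: BinarySignatureSet | Iterable[BinarySignatureSet],
    params: CloneCallParams | None = None,
    metadata: pd.DataFrame | None = None,
) -> CloneTable:
    """Partition cells into clones by thresholded Jaccard similarity.

    Parameters
    ----------
    signatures
        One :class:`BinarySignatureSet` or an iterable of them (at most one
        per modality); cell identifiers must be globally unique.
    params
        Thresholds; defaults to ``CloneCallParams()`` (0.6 intra / 0.5 cross).
    metadata
        Optional per-cell frame indexed by cell with any of the columns
        ``time_point`` and ``sample``; copied into the clone table.
    """
    if params is None:
        params = CloneCallParams()
    if isinstance(signatures, BinarySignatureSet):
        sig_sets = [signatures]
    else:
        sig_sets = list(signatures)

    cells: list[str] = []
    sigs: list[frozenset[str]] = []
    modality: list[str] = []
    seen: set[str] = set()
    for ss in sig_sets:
        for cell, sig in ss.signatures.items():
            if cell in seen:
                raise ValueError(f"duplicated cell identifier {cell!r}")
            seen.add(cell)
            cells.append(cell)
            sigs.append(sig)
            modality.append(ss.modality or "NA")

    n = len(cells)
    if n == 0:
        return CloneTable(pd.DataFrame(columns=CLONE_TABLE_COLUMNS))

    # sparse binary cells x tags matrix over the union tag universe
    tag_index: dict[str, int] = {}
    rows, cols = [], []
    for i, sig in enumerate(sigs):
        for t in sig:
            j = tag_index.setdefault(t, len(tag_index))
            rows.append(i)
            cols.append(j)
    B = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(n, max(len(tag_index), 1)),
    )
    sizes = np.asarray(B.sum(axis=1)).ravel()
    inter = sp.triu(B @ B.T, k=1).tocoo()

    same_modality = np.array(
        [modality[i] == modality[j] for i, j in zip(inter.row, inter.col)]
    ) if inter.nnz else np.array([], dtype=bool)
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    jac = inter.data / union
    tau = np.where(same_modality, params.tau_intra, params.tau_cross)
    keep = jac >= tau if params.inclusive else jac > tau

    adj = sp.coo_matrix(
        (np.ones(int(keep.sum())), (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)

    # deterministic clone ids: by descending size, then smallest member cell
    comp_members: dict[int, list[str]] = {}
    for cell, lab in zip(cells, labels):
        comp_members.setdefault(int(lab), []).append(cell)
    order = sorted(comp_members, key=lambda c: (-len(comp_members[c]), min(comp_members[c])))
    remap = {lab: cid for cid, lab in enumerate(order)}

    df = pd.DataFrame(
        {
            "clone_id": [remap[int(l)] for l in labels],
            "cell": cells,
            "modality": modality,
            "time_point": pd.NA,
            "sample": pd.NA,
            "fate_label": pd.NA,
            "fate_bias": np.nan,
            "tie_flag": False,
        }
    )
    if metadata is not None:
        for col in ("time_point", "sample"):
            if col in metadata.columns:
                df[col] = df["cell"].map(metadata[col]).values
    df = df.sort_values(["clone_id", "cell"], kind="stable").reset_index(drop=True)
    return CloneTable(df)


def assign_clone_fate(
    clones: CloneTable,
    cell_types: Mapping[str, str],
    fate_timepoints: Iterable[str],
    grouping: Mapping[str, str] | None = None,
) -> CloneTable:
    """Annotate clones with fate labels and fate bias from fate-time-point siblings.

    fate_label is the modal *grouped* cell type among siblings captured at
    ``fate_timepoints`` (``grouping`` maps raw types to merged lineages,
    e.g. Ery -> Ery/Meg; identity when absent); fate_bias is the fraction of
    those siblings in the modal group. Modal-count ties are broken toward
    the group containing the raw type with the larger count, then
    lexicographically, with ``tie_flag`` set. Clones without fate siblings
    stay unlabeled.
    """
    fate_tp = set(fate_timepoints)
    grouping = dict(grouping or {})
    df = clones.cells.copy()
    fate_label = {}
    fate_bias = {}
    tie_flag = {}
    for cid, grp in df.groupby("clone_id"):
        siblings = grp.loc[grp["time_point"].isin(fate_tp), "cell"].tolist()
        if not siblings:
            continue
        raw_counts: Counter[str] = Counter()
        for cell in siblings:
            if cell not in cell_types:
                raise ValueError(f"cell {cell!r} lacks a cell-type annotation")
            raw_counts[cell_types[cell]] += 1
        grouped: Counter[str] = Counter()
        for raw, c in raw_counts.items():
            grouped[grouping.get(raw, raw)] += c
        top = max(grouped.values())
        candidates = sorted(g for g, c in grouped.items() if c == top)
        tied = len(candidates) > 1
        if tied:
            # prefer the group whose dominant raw type is itself most numerous
            best_raw = {
                g: max(c for r, c in raw_counts.items() if grouping.get(r, r) == g)
                for g in candidates
            }
            top_raw = max(best_raw.values())
            candidates = sorted(g for g in candidates if best_raw[g] == top_raw)
        fate_label[cid] = candidates[0]
        fate_bias[cid] = top / len(siblings)
        tie_flag[cid] = tied
    df["fate_label"] = df["clone_id"].map(fate_label)
    df["fate_bias"] = df["clone_id"].map(fate_bias)
    df["tie_flag"] = df["clone_id"].map(lambda c: bool(tie_flag.get(c, False)))
    return CloneTable(df)


def observed_homoplasy(
    rep1: BinarySignatureSet, rep2: BinarySignatureSet
) -> float:
    """Fraction of cells whose exact signature also occurs in the other replicate.

    Two biological replicates are infected independently, so any signature
    appearing in both replicates must be a barcode collision (homoplasy),
    not shared descent. Counts cells (both replicates pooled) whose
    signature set-equals a signature in the other replicate.
    """
    if not rep1.signatures or not rep2.signatures:
        raise ValueError("replicates must be nonempty")
    sigs1 = set(rep1.signatures.values())
    sigs2 = set(rep2.signatures.values())
    n_hits = sum(1 for s in rep1.signatures.values() if s in sigs2)
    n_hits += sum(1 for s in rep2.signatures.values() if s in sigs1)
    return n_hits / (len(rep1.signatures) + len(rep2.signatures))


def clonal_correlation(
    expr: pd.DataFrame,
    activity: pd.DataFrame,
    clones: CloneTable,
    min_members: int = 1,
) -> tuple[pd.Series, pd.DataFrame]:
    """Spearman correlation of clone-averaged expression vs accessibility-derived activity.

    Averages ``expr`` over each clone's RNA members and ``activity`` over
    its ATAC members (both cells x features over a shared feature axis),
    then correlates the clone-level profiles: intraclonal = corr(expr_c,
    activity_c) per clone, interclonal = corr(expr_c, activity_d) for every
    ordered pair c != d. Clones lacking members in either matrix are
    skipped. Within-clone agreement exceeding between-clone agreement is
    the expected signature of heritable clone-specific state.
    """
    if list(expr.columns) != list(activity.columns):
        raise ValueError("expr and activity must share the feature axis")
    expr_means = {}
    act_means = {}
    for cid, grp in clones.cells.groupby("clone_id"):
        rna = [c for c in grp.loc[grp["modality"] == "RNA", "cell"] if c in expr.index]
        atac = [
            c for c in grp.loc[grp["modality"] == "ATAC", "cell"] if c in activity.index
        ]
        if len(rna) >= min_members and len(atac) >= min_members:
            expr_means[cid] = expr.loc[rna].mean(axis=0).to_numpy()
            act_means[cid] = activity.loc[atac].mean(axis=0).to_numpy()
    intra = {}
    inter_rows = []
    for c in expr_means:
        intra[c] = float(spearmanr(expr_means[c], act_means[c]).statistic)
        for d in act_means:
            if d != c:
                rho = float(spearmanr(expr_means[c], act_means[d]).statistic)
                inter_rows.append((c, d, rho))
    return (
        pd.Series(intra, name="intraclonal_rho"),
        pd.DataFrame(inter_rows, columns=["expr_clone", "activity_clone", "rho"]),
    )
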