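"""Pairwise sequence distances and the neighbor-joining identification tree.

Distances follow standard barcode practice: pairwise deletion of any site
where either sequence carries a gap or an IUPAC ambiguity code, transitions
(A<->G, C<->T) separated from transversions, and the Kimura two-parameter
correction

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the transition and transversion proportions over the
compared sites.  Sequences are assumed co-aligned over the barcode region;
unequal lengths are an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .records import BarcodeRecord
from .tree import TreeNode

# Encoding: A=0, G=1, C=2, T=3 (so transition <=> same value // 2),
# anything ambiguous or a gap = 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _LUT[ord(_b)] = _i


class SaturationError(ValueError):
    """K2P log argument fell to or below zero (distance undefined)."""


class ComparisonError(ValueError):
    """No comparable sites, or sequences of unequal length."""


@dataclass(frozen=True)
class PairwiseComparison:
    sites_compared: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.sites_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.sites_compared

    @property
    def p_distance(self) -> float:
        return (self.transitions + self.transversions) / self.sites_compared


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences into a (n, L) uint8 matrix."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ComparisonError(f"sequences of unequal length: {sorted(lengths)}")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _LUT[arr].reshape(len(seqs), -1)


def compare_pair(seq_a: str, seq_b: str) -> PairwiseComparison:
    """Count compared sites, transitions and transversions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ComparisonError(
            f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    enc = encode_sequences([seq_a, seq_b])
    a, b = enc[0], enc[1]
    valid = (a != 255) & (b != 255)
    n = int(valid.sum())
    if n == 0:
        raise ComparisonError("no comparable sites")
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseComparison(sites_compared=n, transitions=ts, transversions=tv)


def k2p_distance(cmp: PairwiseComparison) -> float:
    """Kimura two-parameter distance in substitutions per site."""
    p, q = cmp.P, cmp.Q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair (P={p:.4f}, Q={q:.4f}): K2P undefined"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(cmp: PairwiseComparison) -> float:
    return cmp.p_distance


def similarity_percent(cmp: PairwiseComparison, *, rounded: bool = True) -> float:
    """Percent identity over compared sites, 100 * (1 - p).

    With ``rounded`` (the default) the value is reported to two decimals,
    rounding half away from zero, mirroring the report print format.
    """
    value = 100.0 * (1.0 - cmp.p_distance)
    if not rounded:
        return value
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal; np.inf where saturated
    metric: str  # "p" | "k2p"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.metric not in ("p", "k2p"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def saturated(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def has_saturation(self) -> bool:
        return bool(self.saturated.any())

    def index_of(self, record_id: str) -> int:
        try:
            return self.ids.index(record_id)
        except ValueError:
            raise KeyError(f"unknown record id {record_id!r}") from None

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])


def _pairwise_counts(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n_sites, transitions, transversions) for all pairs.

    Row-blocked broadcasting: O(n^2 L / 2) byte operations.
    """
    n = enc.shape[0]
    valid = enc != 255
    purine = enc >> 1  # 0 for A/G, 1 for C/T; junk where invalid
    sites = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = v & (enc[i] != enc[i + 1 :])
        same_class = diff & (purine[i] == purine[i + 1 :])
        sites[i, i + 1 :] = v.sum(axis=1)
        ts[i, i + 1 :] = same_class.sum(axis=1)
        tv[i, i + 1 :] = diff.sum(axis=1) - ts[i, i + 1 :]
    sites += sites.T
    ts += ts.T
    tv += tv.T
    return sites, ts, tv


def distance_matrix(records: Sequence[BarcodeRecord], metric: str = "k2p") -> DistanceMatrix:
    """Full symmetric distance matrix in input order.

    Saturated pairs (K2P log argument <= 0) are flagged as ``inf`` rather
    than raising, so downstream stages can report the offending pairs.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    enc = encode_sequences([r.sequence for r in records])
    sites, ts, tv = _pairwise_counts(enc)
    n = len(records)
    if (sites[~np.eye(n, dtype=bool)] == 0).any():
        raise ComparisonError("some pair has no comparable sites")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / sites
        Q = tv / sites
        if metric == "p":
            vals = P + Q
        else:
            arg = (1.0 - 2.0 * P - Q) * np.sqrt(np.maximum(1.0 - 2.0 * Q, 0.0))
            vals = np.where(arg > 0.0, -0.5 * np.log(np.where(arg > 0.0, arg, 1.0)), np.inf)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(ids=tuple(r.record_id for r in records), values=vals, metric=metric)


def similarity_matrix(
    queries: Sequence[BarcodeRecord], references: Sequence[BarcodeRecord]
) -> np.ndarray:
    """Unrounded percent identity of every query against every reference."""
    nq = len(queries)
    enc = encode_sequences([r.sequence for r in list(queries) + list(references)])
    q_enc, r_enc = enc[:nq], enc[nq:]
    q_valid, r_valid = q_enc != 255, r_enc != 255
    sims = np.empty((nq, len(references)))
    for i in range(nq):
        v = q_valid[i] & r_valid
        diff = (v & (q_enc[i] != r_enc)).sum(axis=1)
        sites = v.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sims[i] = 100.0 * (1.0 - diff / sites)
    return sims


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q-criterion are broken by the lowest (row, column) index
    pair in current matrix order.  Negative branch lengths are clamped to
    zero with the excess moved to the sister branch.  The result is the
    unrooted NJ tree returned with its final trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.has_saturation:
        sat = np.argwhere(dm.saturated)
        pairs = [(dm.ids[i], dm.ids[j]) for i, j in sat if i < j]
        raise SaturationError(f"saturated pairs in matrix: {pairs}")

    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among the minima, in current order
        flat = np.argmin(q)
        qi, qj = divmod(int(flat), m)
        qmin = q[qi, qj]
        ties = np.argwhere(q <= qmin + 1e-12)
        qi, qj = min((int(i), int(j)) for i, j in ties)
        if qi > qj:
            qi, qj = qj, qi

        i_idx, j_idx = active[qi], active[qj]
        dij = sub[qi, qj]
        li = 0.5 * dij + (r[qi] - r[qj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the excess to the sister branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0

        parent = TreeNode()
        parent.children.append((nodes[i_idx], li))
        parent.children.append((nodes[j_idx], lj))

        # distances from the new node to the rest
        new_row = 0.5 * (D[i_idx, :] + D[j_idx, :] - dij)
        D[i_idx, :] = new_row
        D[:, i_idx] = new_row
        D[i_idx, i_idx] = 0.0
        nodes[i_idx] = parent
        active.remove(j_idx)

    # final trifurcation: three-point formulas
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = TreeNode()
    root.children.append((nodes[a], la))
    root.children.append((nodes[b], lb))
    root.children.append((nodes[c], lc))
    return root
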