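"""Weighted chi-squared coevolution scoring and the strong-pair
allostery screen.

Allosteric communication between protein regions (here the L2 loop of the
beta-cap domain and the [2Fe-2S] binding region of NEET proteins) leaves a
signature of jointly mutating residue pairs in a family alignment.  The
screen scores every column pair of an MSA with an identity-weighted
chi-squared association statistic over the 20-letter amino-acid alphabet,
min-max normalizes the score matrix to [0, 1], and retains pairs that
(i) score above an absolute threshold (default 0.7), (ii) fall in the top
fraction of all scores (default 30%), and (iii) are *not* in close spatial
proximity in a representative 3-D structure — distant strong pairs being
the allostery candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Alignment",
    "CoevolutionMatrix",
    "AllosteryReport",
    "sequence_weights",
    "weighted_chi2",
    "coevolution_matrix",
    "normalize_matrix",
    "strong_pairs",
    "residue_min_distances",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CODE = 20
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class Alignment:
    """An MSA over the 20-amino-acid alphabet plus gap.

    ``codes`` is (n_seqs, L) int8 with 0..19 residues and 20 for gaps or
    unknowns; ``ref_numbering`` maps each column to a residue number of
    the reference sequence (NaN-free only for reference non-gap columns).
    """

    codes: np.ndarray
    ids: list[str]
    ref_id: str | None = None
    ref_numbering: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be (n_seqs, L)")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("ids and codes disagree on sequence count")
        if self.weights is not None and (np.asarray(self.weights) <= 0).any():
            raise ValueError("sequence weights must be positive")

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, seqs: list[str], ids=None, ref_id=None,
                       ref_start: int = 1) -> "Alignment":
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("aligned sequences must have equal length")
        ids = ids or [f"seq{i}" for i in range(len(seqs))]
        codes = np.array([[_CODE.get(c.upper(), GAP_CODE) for c in s]
                          for s in seqs], dtype=np.int8)
        aln = cls(codes=codes, ids=list(ids), ref_id=ref_id)
        ref = ref_id or ids[0]
        ref_row = codes[list(ids).index(ref)]
        numbering = np.full(codes.shape[1], -1, dtype=int)
        num = ref_start
        for col in range(codes.shape[1]):
            if ref_row[col] != GAP_CODE:
                numbering[col] = num
                num += 1
        aln.ref_id = ref
        aln.ref_numbering = numbering
        return aln

    @classmethod
    def from_file(cls, path, fmt: str = "fasta", ref_id=None,
                  ref_start: int = 1) -> "Alignment":
        """Read FASTA or Stockholm via Bio.AlignIO."""
        from Bio import AlignIO
        msa = AlignIO.read(path, fmt)
        seqs = [str(rec.seq) for rec in msa]
        ids = [rec.id for rec in msa]
        return cls.from_sequences(seqs, ids=ids, ref_id=ref_id,
                                  ref_start=ref_start)


def sequence_weights(aln: Alignment, identity_cutoff: float = 0.8) -> np.ndarray:
    """Identity-based weights: 1 / (number of sequences at >= cutoff
    identity to this one, self included)."""
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    X = aln.codes
    n = aln.n_seqs
    counts = np.zeros(n)
    # chunked all-vs-all identity over full alignment length
    chunk = max(1, 2_000_000 // (n * X.shape[1] + 1))
    for s in range(0, n, chunk):
        ident = (X[s:s + chunk, None, :] == X[None, :, :]).mean(axis=2)
        counts[s:s + chunk] = (ident >= identity_cutoff).sum(axis=1)
    return 1.0 / counts


def weighted_chi2(aln: Alignment, i: int, j: int,
                  weights: np.ndarray | None = None) -> float:
    """Weighted chi-squared association between columns ``i`` and ``j``.

    Rows with a gap in either column are dropped (pairwise deletion; gaps
    never act as a 21st symbol).  With weighted joint counts O_ab and
    independence expectations E_ab = row_a * col_b / N_eff, returns
    ``sum (O-E)^2 / E`` over cells with E > 0.  Fewer than two ungapped
    rows give 0 with a warning.
    """
    w = weights if weights is not None else (
        aln.weights if aln.weights is not None else np.ones(aln.n_seqs))
    a = aln.codes[:, i].astype(np.intp)
    b = aln.codes[:, j].astype(np.intp)
    ok = (a != GAP_CODE) & (b != GAP_CODE)
    if ok.sum() < 2:
        warnings.warn(f"columns {i},{j}: fewer than 2 ungapped rows; score 0")
        return 0.0
    return _chi2_from_codes(a[ok], b[ok], np.asarray(w, float)[ok])


def _chi2_from_codes(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    O = np.bincount(a * 20 + b, weights=w, minlength=400).reshape(20, 20)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    n_eff = row.sum()
    E = np.outer(row, col) / n_eff
    mask = E > 0
    return float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())


@dataclass
class CoevolutionMatrix:
    """Symmetric normalized score matrix with threshold metadata."""

    scores: np.ndarray               # L x L in [0, 1], diagonal NaN
    raw_min: float
    raw_max: float
    method: str = "minmax"
    score_min: float = 0.7
    top_fraction: float = 0.30

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices_from(self.scores, k=1)
        return self.scores[iu]


def coevolution_matrix(aln: Alignment, weights: np.ndarray | None = None,
                       normalize: str = "minmax") -> CoevolutionMatrix:
    """Raw weighted chi-squared for all column pairs, then normalization."""
    w = weights if weights is not None else (
        aln.weights if aln.weights is not None else np.ones(aln.n_seqs))
    w = np.asarray(w, float)
    L = aln.length
    raw = np.zeros((L, L))
    codes = aln.codes.astype(np.intp)
    gap = codes == GAP_CODE
    any_gap = gap.any()
    for i in range(L):
        ai = codes[:, i]
        for j in range(i + 1, L):
            if any_gap:
                ok = ~gap[:, i] & ~gap[:, j]
                if ok.sum() < 2:
                    continue
                raw[i, j] = _chi2_from_codes(ai[ok], codes[ok, j], w[ok])
            else:
                raw[i, j] = _chi2_from_codes(ai, codes[:, j], w)
            raw[j, i] = raw[i, j]
    return normalize_matrix(raw, method=normalize)


def normalize_matrix(raw: np.ndarray, method: str = "minmax") -> CoevolutionMatrix:
    """Rescale a raw score matrix to [0, 1] over its off-diagonal entries.

    ``minmax`` applies an affine map (rank order preserved); ``rank``
    maps scores to their empirical quantile, an alternative when the
    upstream normalization is unknown.  A constant matrix maps to 0.5
    everywhere with a warning.
    """
    raw = np.asarray(raw, float)
    if not np.isfinite(raw).all():
        raise ValueError("raw score matrix contains non-finite entries")
    L = raw.shape[0]
    iu = np.triu_indices(L, k=1)
    off = raw[iu]
    lo, hi = float(off.min()), float(off.max())
    out = np.full((L, L), np.nan)
    if hi - lo < 1e-300:
        warnings.warn("constant score matrix; normalized scores set to 0.5")
        vals = np.full_like(off, 0.5)
    elif method == "minmax":
        vals = (off - lo) / (hi - lo)
    elif method == "rank":
        order = off.argsort().argsort()
        vals = order / max(1, len(off) - 1)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    out[iu] = vals
    out[(iu[1], iu[0])] = vals
    return CoevolutionMatrix(scores=out, raw_min=lo, raw_max=hi, method=method)


# ---------------------------------------------------------------------------
# structural filter

@dataclass
class AllosteryReport:
    """Residue pairs surviving the score / top-fraction / distance screen."""

    pairs: pd.DataFrame
    params: dict
    skipped: list = field(default_factory=list)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            for k, v in self.params.items():
                fh.write(f"# {k} = {v}\n")
            self.pairs.to_csv(fh, sep="\t", index=False)


def residue_min_distances(structure, residue_numbers: list[int]) -> dict:
    """Minimal heavy-atom coordinates per residue number (first chain with
    that number wins); returns {resnum: (N_atoms, 3) array, Angstrom}."""
    from .sites import _first_model, AMINO3
    model = _first_model(structure)
    coords = {}
    for chain in model:
        for res in chain:
            num = res.get_id()[1]
            if res.get_resname() not in AMINO3 or num in coords:
                continue
            xyz = np.array([a.coord for a in res
                            if not a.get_name().startswith("H")], dtype=float)
            if len(xyz):
                coords[num] = xyz
    return {n: coords[n] for n in residue_numbers if n in coords}


def strong_pairs(matrix: CoevolutionMatrix, structure,
                 ref_numbering: np.ndarray,
                 score_min: float = 0.7, top_fraction: float = 0.30,
                 min_seq_sep: int = 5, min_distance_A: float = 5.0,
                 filters: str = "both") -> AllosteryReport:
    """Retain coevolving pairs that are strong *and* spatially distant.

    A pair passes when its normalized score exceeds ``score_min``, it lies
    within the top ``top_fraction`` of all off-diagonal scores (both
    filters conjunctive by default; ``filters`` in {"both", "score",
    "top"} relaxes to one), its sequence separation is at least
    ``min_seq_sep``, and the minimal heavy-atom distance between the two
    residues in the structure is at least ``min_distance_A`` (pairs in
    close proximity are contacts, not allostery candidates).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    S = matrix.scores
    L = S.shape[0]
    off = matrix.off_diagonal()
    top_thr = float(np.quantile(off, 1 - top_fraction))
    nums = np.asarray(ref_numbering)
    wanted = [int(n) for n in np.unique(nums) if n > 0]
    res_xyz = residue_min_distances(structure, wanted)

    rows, skipped = [], []
    iu = np.triu_indices(L, k=1)
    for i, j in zip(*iu):
        s = S[i, j]
        if np.isnan(s):
            continue
        if filters in ("both", "score") and not s > score_min:
            continue
        if filters in ("both", "top") and not s >= top_thr:
            continue
        ni, nj = int(nums[i]), int(nums[j])
        if ni < 0 or nj < 0 or ni not in res_xyz or nj not in res_xyz:
            skipped.append((i, j, "unmappable residue number"))
            continue
        if abs(ni - nj) < min_seq_sep:
            continue
        a, b = res_xyz[ni], res_xyz[nj]
        dmin = float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2)
                             .sum(-1).min()))
        if dmin < min_distance_A:
            continue
        rows.append({"col_i": int(i), "col_j": int(j), "res_i": ni,
                     "res_j": nj, "score": float(s), "min_dist_A": dmin,
                     "seq_sep": abs(ni - nj)})
    df = pd.DataFrame(rows, columns=["col_i", "col_j", "res_i", "res_j",
                                     "score", "min_dist_A", "seq_sep"])
    df = df.sort_values("score", ascending=False).reset_index(drop=True)
    return AllosteryReport(
        pairs=df,
        params={"score_min": score_min, "top_fraction": top_fraction,
                "top_threshold": top_thr, "min_seq_sep": min_seq_sep,
                "min_distance_A": min_distance_A, "filters": filters,
                "normalization": matrix.method},
        skipped=skipped)
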