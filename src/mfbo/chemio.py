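"""Molecule parsing, fingerprints, similarity, clustering, and substructure filters.

This module is the shared chemistry layer: every other part of the package
represents a molecule as a :class:`MoleculeRecord` carrying a circular
(Morgan-type) substructure fingerprint — radius 2, 1024 bits, binary, no
chirality — and measures structural similarity with the Tanimoto coefficient
on those fingerprints.

Conventions
-----------
* Tanimoto similarity of two all-zero ("featureless") fingerprints is defined
  as 1.0; the choice is logged once per process.
* Set diversity D of a fingerprint collection is one minus the mean pairwise
  Tanimoto similarity; for very large sets the mean is estimated over a
  seeded uniform sample of unordered pairs (``pair_cap``, default 50,000).
* Clustering uses PAM-style k-medoids over Tanimoto distance (1 - similarity)
  with a deterministic greedy build plus seeded random restarts, so medoid
  molecules are always available for amortized scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit parse warnings are reported through our own channel

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 1024

_ZERO_PAIR_LOGGED = False

__all__ = [
    "MoleculeRecord",
    "SubstructureFilterReport",
    "SmartsPattern",
    "fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "set_diversity",
    "candidate_diversity",
    "cluster_kmedoids",
    "filter_substructures",
    "default_filter_patterns",
    "parse_library",
    "write_library",
    "read_smiles_file",
    "read_smarts_file",
]


# ---------------------------------------------------------------------------
# fingerprints and records
# ---------------------------------------------------------------------------

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def fingerprint(
    smiles: str, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> np.ndarray:
    """Binary circular substructure fingerprint of ``smiles``.

    Deterministic given ``(smiles, radius, n_bits)``; raises ``ValueError``
    for SMILES that do not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    bv = _generator(radius, n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


@dataclass(frozen=True)
class MoleculeRecord:
    """A library molecule: identifier, SMILES, and its binary fingerprint."""

    id: str
    smiles: str
    fingerprint: np.ndarray = field(repr=False)

    @classmethod
    def from_smiles(
        cls,
        mol_id: str,
        smiles: str,
        radius: int = DEFAULT_FP_RADIUS,
        n_bits: int = DEFAULT_FP_BITS,
    ) -> "MoleculeRecord":
        return cls(id=mol_id, smiles=smiles, fingerprint=fingerprint(smiles, radius, n_bits))


# ---------------------------------------------------------------------------
# similarity and diversity
# ---------------------------------------------------------------------------


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary vectors.

    Both-all-zero pairs are defined to have similarity 1.0 (two featureless
    molecules are treated as indistinguishable).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        global _ZERO_PAIR_LOGGED
        if not _ZERO_PAIR_LOGGED:
            logger.info("tanimoto: all-zero fingerprint pair, returning 1.0 by convention")
            _ZERO_PAIR_LOGGED = True
        return 1.0
    return inter / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Tanimoto similarity between two stacks of binary fingerprints.

    ``fps_a`` is (n, L); ``fps_b`` defaults to ``fps_a``. Returns (n, m)
    float64. Vectorized via inner products, so it is the workhorse behind the
    Tanimoto kernel.
    """
    A = (np.asarray(fps_a) != 0).astype(np.float64)
    B = A if fps_b is None else (np.asarray(fps_b) != 0).astype(np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    pa = A.sum(axis=1)
    pb = B.sum(axis=1)
    union = pa[:, None] + pb[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return sim


def _pair_index_decode(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat unordered-pair indices k in [0, n(n-1)/2) to (i, j), i<j."""
    k = k.astype(np.float64)
    i = np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k)) / 2).astype(np.int64)
    j = (k - i * (2 * n - i - 1) / 2).astype(np.int64) + i + 1
    return i, j


def set_diversity(
    fps: np.ndarray | Sequence[np.ndarray],
    pair_cap: int = 50_000,
    seed: int = 0,
) -> float:
    """Diversity D = 1 - mean pairwise Tanimoto similarity of a fingerprint set.

    Exact when the number of unordered pairs is at most ``pair_cap``;
    otherwise the mean is taken over ``pair_cap`` uniformly sampled pairs
    (without replacement, seeded).
    """
    fps = np.asarray(fps)
    n = fps.shape[0]
    if n < 2:
        raise ValueError("set_diversity requires at least 2 fingerprints")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_cap:
        sim = tanimoto_matrix(fps)
        iu = np.triu_indices(n, k=1)
        return float(1.0 - sim[iu].mean())
    rng = np.random.default_rng(seed)
    ks = rng.choice(n_pairs, size=pair_cap, replace=False)
    i, j = _pair_index_decode(np.asarray(ks), n)
    if n <= 4096:
        sim = tanimoto_matrix(fps)
        return float(1.0 - sim[i, j].mean())
    A = (fps != 0).astype(np.float64)
    pop = A.sum(axis=1)
    sims = np.empty(pair_cap)
    for start in range(0, pair_cap, 8192):  # chunked to bound memory
        sl = slice(start, min(start + 8192, pair_cap))
        inter = np.einsum("ij,ij->i", A[i[sl]], A[j[sl]])
        union = pop[i[sl]] + pop[j[sl]] - inter
        sims[sl] = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return float(1.0 - sims.mean())


def candidate_diversity(fp: np.ndarray, others: np.ndarray | Sequence[np.ndarray]) -> float:
    """One minus the mean Tanimoto similarity of ``fp`` to each of ``others``."""
    others = np.asarray(others)
    if others.ndim != 2 or others.shape[0] == 0:
        raise ValueError("candidate_diversity requires a nonempty collection of others")
    sims = tanimoto_matrix(np.asarray(fp)[None, :], others)[0]
    return float(1.0 - sims.mean())


# ---------------------------------------------------------------------------
# k-medoids clustering (PAM build + swap over Tanimoto distance)
# ---------------------------------------------------------------------------


def _pam_cost(dist: np.ndarray, medoids: np.ndarray) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def _pam_swap(dist: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Iterate best-improvement swaps until no swap lowers total distance."""
    n = dist.shape[0]
    medoids = medoids.copy()
    while True:
        sub = dist[:, medoids]
        order = np.argsort(sub, axis=1)
        d1 = sub[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = sub[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best_delta = -1e-12
        best_swap = None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        if len(non_medoids) == 0:
            return medoids
        for mi, m in enumerate(medoids):
            base = np.where(nearest == mi, d2, d1)  # cost if m is dropped
            # candidate new cost for every h at once: sum_j min(base_j, D[j,h])
            new_costs = np.minimum(base[:, None], dist[:, non_medoids]).sum(axis=0)
            hi = int(np.argmin(new_costs))
            delta = new_costs[hi] - cost
            if delta < best_delta:
                best_delta = delta
                best_swap = (mi, non_medoids[hi])
        if best_swap is None:
            return medoids
        medoids[best_swap[0]] = best_swap[1]


def _pam_greedy_build(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    d_near = dist[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        d_near = np.minimum(d_near, dist[:, nxt])
    return np.array(sorted(medoids))


def cluster_kmedoids(
    fps: np.ndarray | Sequence[np.ndarray],
    k: int,
    seed: int = 0,
    n_restarts: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """PAM k-medoids over Tanimoto distance.

    Returns ``(labels, medoid_indices)``. Restart 0 uses the deterministic
    greedy build; the remaining restarts start from seeded random medoid
    sets. The lowest-total-distance solution wins. Deterministic given seed.
    """
    fps = np.asarray(fps)
    n = fps.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = 1.0 - tanimoto_matrix(fps)
    np.fill_diagonal(dist, 0.0)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            init = _pam_greedy_build(dist, k)
        else:
            init = np.sort(rng.choice(n, size=k, replace=False))
        medoids = _pam_swap(dist, init)
        cost = _pam_cost(dist, medoids)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids)
    medoids = np.sort(best[1])
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, medoids


# ---------------------------------------------------------------------------
# substructure filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmartsPattern:
    """A named SMARTS substructure pattern."""

    name: str
    smarts: str

    def __post_init__(self):
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for pattern {self.name!r}: {self.smarts!r}")
        object.__setattr__(self, "_mol", patt)

    def matches(self, mol: Chem.Mol) -> bool:
        return mol.HasSubstructMatch(self._mol)


class _PainsCatalog:
    """The standard PAINS frequent-hitter catalog, exposed as one named matcher."""

    name = "PAINS"

    def __init__(self) -> None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        self._catalog = FilterCatalog(params)

    def matches(self, mol: Chem.Mol) -> bool:
        return self._catalog.HasMatch(mol)

    def match_name(self, mol: Chem.Mol) -> str:
        entry = self._catalog.GetFirstMatch(mol)
        return f"PAINS:{entry.GetDescription()}" if entry is not None else "PAINS"


# Hydroxamic acids (C(=O)N-O with H or O-substituent) are excluded so that an
# HDAC-inhibitor search cannot converge on the well-known hydroxamate optimum;
# the reactive-group patterns drop functionalities an automated liquid-handling
# platform cannot test safely.
HYDROXAMATE = SmartsPattern("hydroxamate", "[CX3](=O)[NX3][OX2]")
REACTIVE_PATTERNS = (
    SmartsPattern("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    SmartsPattern("sulfonyl_halide", "[SX4](=O)(=O)[F,Cl,Br,I]"),
    SmartsPattern("isocyanate", "[NX2]=C=[OX1]"),
    SmartsPattern("azide", "[NX2]=[NX2+]=[NX1-]"),
)


def default_filter_patterns(include_pains: bool = True) -> list:
    patterns: list = []
    if include_pains:
        patterns.append(_PainsCatalog())
    patterns.append(HYDROXAMATE)
    patterns.extend(REACTIVE_PATTERNS)
    return patterns


@dataclass
class SubstructureFilterReport:
    """Partition of an input library into kept ids and (id, pattern) removals."""

    kept: list[str]
    removed: list[tuple[str, str]]


def filter_substructures(
    mols: Sequence[MoleculeRecord],
    patterns: Sequence | None = None,
) -> SubstructureFilterReport:
    """Remove molecules matching any named substructure pattern.

    ``patterns`` defaults to the PAINS catalog plus the hydroxamate and
    reactive-group patterns. Matching is substructure match, not exact match.
    """
    if patterns is None:
        patterns = default_filter_patterns()
    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for rec in mols:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            removed.append((rec.id, "unparsable"))
            continue
        hit = None
        for patt in patterns:
            if patt.matches(mol):
                hit = patt.match_name(mol) if hasattr(patt, "match_name") else patt.name
                break
        if hit is None:
            kept.append(rec.id)
        else:
            removed.append((rec.id, hit))
    return SubstructureFilterReport(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

#: canonical fidelity level order used across the package
FIDELITY_COLUMNS = ("low", "medium", "high")


@dataclass(frozen=True)
class ColumnMap:
    id: str = "id"
    smiles: str = "smiles"
    low: str = "low"
    medium: str = "medium"
    high: str = "high"


def parse_library(
    path: str | Path,
    columns: ColumnMap = ColumnMap(),
    strict: bool = False,
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_BITS,
) -> tuple[list[MoleculeRecord], dict[tuple[str, int], float]]:
    """Read a delimited-text library (comma or tab) into records + value table.

    Returns ``(records, values)`` where ``values`` maps ``(molecule id,
    fidelity index)`` to the stored assay value (0 = low, 1 = medium,
    2 = high); missing cells are simply absent. Rows whose SMILES do not
    parse are dropped with a warning, or raise in strict mode. Duplicate ids
    raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if columns.smiles not in df.columns:
        raise ValueError(f"missing SMILES column {columns.smiles!r} in {path}")
    if columns.id not in df.columns:
        raise ValueError(f"missing id column {columns.id!r} in {path}")
    ids = df[columns.id].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise ValueError(f"duplicate molecule ids in {path}: {list(dupes)}")
    records: list[MoleculeRecord] = []
    values: dict[tuple[str, int], float] = {}
    fid_cols = [getattr(columns, name) for name in FIDELITY_COLUMNS]
    for row_no, row in df.iterrows():
        mol_id = str(row[columns.id])
        smiles = str(row[columns.smiles])
        try:
            rec = MoleculeRecord.from_smiles(mol_id, smiles, radius, n_bits)
        except ValueError:
            if strict:
                raise ValueError(
                    f"row {row_no} (id={mol_id!r}): unparsable SMILES {smiles!r}"
                ) from None
            logger.warning("row %s (id=%s): unparsable SMILES %r, skipped", row_no, mol_id, smiles)
            continue
        records.append(rec)
        for level, col in enumerate(fid_cols):
            if col in df.columns and pd.notna(row[col]):
                values[(mol_id, level)] = float(row[col])
    return records, values


def write_library(
    path: str | Path,
    records: Sequence[MoleculeRecord],
    values: Mapping[tuple[str, int], float],
    columns: ColumnMap = ColumnMap(),
) -> None:
    """Write records + value table back to the delimited-text library format."""
    rows = []
    for rec in records:
        row = {columns.id: rec.id, columns.smiles: rec.smiles}
        for level, name in enumerate(FIDELITY_COLUMNS):
            if (rec.id, level) in values:
                row[getattr(columns, name)] = values[(rec.id, level)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a one-SMILES-per-line file (blank lines and ``#`` comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def read_smarts_file(path: str | Path) -> list[SmartsPattern]:
    """Read ``name<TAB>smarts`` pattern lines; invalid patterns raise at load."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        patterns.append(SmartsPattern(name, smarts))
    return patterns
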