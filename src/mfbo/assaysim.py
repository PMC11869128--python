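"""Hill-equation assay simulation and the retrospective measurement oracle.

Single-point percent inhibition at a screening concentration ``[L]`` is
related to a compound's IC50 through the noncooperative Hill equation
(Hill coefficient 1 unless stated):

    inhibition% = 100 / (1 + (IC50 / [L])^h)

so that inhibition is exactly 50% at ``[L] = IC50``. The oracle answers
(molecule, fidelity) queries from stored ground truth — a docking-like low
value, and a high value stored as pIC50 = -log10(IC50 in molar) — adding
seeded Gaussian assay noise per fidelity. Medium-fidelity answers are the
Hill transform of the ground-truth potency at the screen concentration
(default 20 uM, matching a plate-reader single-point assay), with noise
clipped into [0, 100].

Each (molecule, fidelity) query uses its own hashed noise substream and is
memoized, so answers do not depend on query order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .seeding import substream

if TYPE_CHECKING:  # pragma: no cover
    from .benchdata import LibraryDataset

__all__ = [
    "NoiseConfig",
    "AssayOracle",
    "hill_inhibition",
    "ic50_from_inhibition",
    "make_oracle",
    "inject_decoys",
    "DEFAULT_SCREEN_CONC",
    "DECOY_PIC50_SENTINEL",
]

DEFAULT_SCREEN_CONC = 2.0e-5  # molar; 20 uM single-point screen
DECOY_PIC50_SENTINEL = 3.0  # ~1 mM: negligible activity for presumed inactives


def hill_inhibition(ic50: float, conc: float, hill: float = 1.0) -> float:
    """Percent inhibition at ligand concentration ``conc`` (both molar).

    Strictly increasing in ``conc`` and strictly decreasing in ``ic50``;
    equals 50.0 exactly at ``conc == ic50``.
    """
    ic50 = np.asarray(ic50, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(ic50 <= 0) or np.any(conc <= 0) or hill <= 0:
        raise ValueError("ic50, conc and hill must all be positive")
    out = 100.0 / (1.0 + (ic50 / conc) ** hill)
    return float(out) if out.ndim == 0 else out


def ic50_from_inhibition(percent: float, conc: float, hill: float = 1.0) -> float:
    """Exact inverse of :func:`hill_inhibition`: IC50 implied by one single point."""
    percent = np.asarray(percent, dtype=float)
    if np.any(percent <= 0) or np.any(percent >= 100):
        raise ValueError("percent inhibition must lie strictly inside (0, 100)")
    if conc <= 0 or hill <= 0:
        raise ValueError("conc and hill must be positive")
    out = conc * (100.0 / percent - 1.0) ** (1.0 / hill)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian assay-noise SDs per fidelity.

    ``low_fraction_of_range`` expresses docking-score noise as a fraction of
    the ground-truth low-value range; medium noise is in percentage points;
    high noise in pIC50 units.
    """

    low_fraction_of_range: float = 0.10
    medium_sd: float = 5.0
    high_sd: float = 0.1

    def __post_init__(self):
        if min(self.low_fraction_of_range, self.medium_sd, self.high_sd) < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class AssayOracle:
    """Retrospective measurement oracle over stored per-molecule ground truth."""

    low_truth: dict[str, float]  # docking-like score, raw orientation
    pic50_truth: dict[str, float]  # potency as pIC50
    screen_conc: float = DEFAULT_SCREEN_CONC
    hill: float = 1.0
    low_sd: float = 0.0  # absolute SD, resolved from NoiseConfig at construction
    medium_sd: float = 5.0
    high_sd: float = 0.1
    seed: int = 0
    _cache: dict[tuple[str, int], float] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.screen_conc <= 0:
            raise ValueError("screen concentration must be positive")

    def query(self, molecule_id: str, fidelity: int) -> float:
        """Measured value for a (molecule, fidelity) pair; memoized and
        order-independent (noise comes from a per-pair hashed substream)."""
        key = (molecule_id, fidelity)
        if key in self._cache:
            return self._cache[key]
        if molecule_id not in self.pic50_truth:
            raise KeyError(f"unknown molecule {molecule_id!r}")
        rng = substream(self.seed, "oracle", molecule_id, fidelity)
        if fidelity == 0:
            value = self.low_truth[molecule_id] + rng.normal(0.0, self.low_sd or 0.0)
        elif fidelity == 1:
            ic50 = 10.0 ** (-self.pic50_truth[molecule_id])
            clean = hill_inhibition(ic50, self.screen_conc, self.hill)
            value = float(np.clip(clean + rng.normal(0.0, self.medium_sd), 0.0, 100.0))
        elif fidelity == 2:
            value = self.pic50_truth[molecule_id] + rng.normal(0.0, self.high_sd)
        else:
            raise ValueError(f"fidelity index {fidelity} out of range")
        self._cache[key] = float(value)
        return self._cache[key]


def make_oracle(
    dataset: "LibraryDataset",
    screen_conc: float | None = None,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    hill: float = 1.0,
) -> AssayOracle:
    """Build the measurement oracle from a dataset's ground truth.

    ``screen_conc`` defaults to the concentration recorded in the dataset's
    metadata (synthetic libraries record the screen their medium column was
    realized at) and otherwise to the 20 uM package default. Low-fidelity
    noise SD is ``noise.low_fraction_of_range`` times the range of the
    stored low values.
    """
    if screen_conc is None:
        screen_conc = getattr(dataset, "meta", {}).get("screen_conc", DEFAULT_SCREEN_CONC)
    low = dict(zip(dataset.ids, dataset.low))
    high = dict(zip(dataset.ids, dataset.high))
    low_range = float(np.ptp(dataset.low)) if len(dataset.low) > 1 else 0.0
    return AssayOracle(
        low_truth=low,
        pic50_truth=high,
        screen_conc=screen_conc,
        hill=hill,
        low_sd=noise.low_fraction_of_range * low_range,
        medium_sd=noise.medium_sd,
        high_sd=noise.high_sd,
        seed=seed,
    )


def inject_decoys(
    dataset: "LibraryDataset",
    decoy_smiles: Sequence[str],
    fraction: float,
    seed: int = 0,
    inactive_pic50: float = DECOY_PIC50_SENTINEL,
) -> "LibraryDataset":
    """Dilute a library with presumed-inactive decoys.

    The result contains ``round(fraction * final_size)`` decoys, i.e. the
    actives are topped up so that decoys make up ``fraction`` of the final
    library. Decoys receive plausible docking-like low values (resampled
    from the actives' empirical low distribution — a docking score is still
    computed for a decoy) and a fixed negligible-activity pIC50 sentinel, so
    they can never enter the top-N% label set.
    """
    from .benchdata import LibraryDataset  # local import: benchdata imports assaysim
    from .chemio import MoleculeRecord

    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return dataset
    n_act = len(dataset.ids)
    final_size = int(round(n_act / (1.0 - fraction)))
    n_decoys = int(round(fraction * final_size))
    if n_decoys > len(decoy_smiles):
        raise ValueError(
            f"need {n_decoys} decoys but only {len(decoy_smiles)} SMILES supplied"
        )
    rng = substream(seed, "decoys")
    picked = rng.choice(len(decoy_smiles), size=n_decoys, replace=False)
    low_scores = rng.choice(np.asarray(dataset.low), size=n_decoys, replace=True)
    records = list(dataset.molecules)
    low = list(dataset.low)
    high = list(dataset.high)
    for j, (idx, low_val) in enumerate(zip(picked, low_scores)):
        rec = MoleculeRecord.from_smiles(f"decoy_{j:04d}", decoy_smiles[int(idx)])
        records.append(rec)
        low.append(float(low_val))
        high.append(float(inactive_pic50))
    return LibraryDataset(
        molecules=records,
        low=np.array(low),
        high=np.array(high),
        medium=None,
        provenance=dataset.provenance + "+decoys",
    )
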