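"""Rigid-body superposition and weighted RMSD over HLA structure models.

Two discrepancy scores are computed between a pair of single-chain HLA
structure models (one Cα coordinate per residue, mature-protein 1-based
numbering):

* **coordinate RMSD** — weighted RMSD after optimal superposition over all
  residues common to both models;
* **revised RMSD** — the same quantity restricted to the functional
  recognition region of the molecule (the peptide-binding groove and
  TCR-contact stretches), excluding random-coil residues whose variation
  carries no recognition signal.

The default recognition regions are, in mature-protein numbering,
residues 3-13, 20-38, 45-85, 92-103, 109-127 and 132-178 for class I
molecules and 9-18, 21-30, 33-39, 42-47 and 50-87 for class II.

The superposition is the weighted Kabsch solution: the proper rotation R
and translation t minimising sum_i w_i |x_i - R y_i - t|^2, solved by SVD
of the weighted cross-covariance with the determinant-sign correction.
The RMSD reported is sqrt(sum_i w_i |x_i - y_i|^2 / sum_i w_i), which with
unit weights reduces to the ordinary RMSD over N residue pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .nomenclature import Allele

__all__ = [
    "StructureModel",
    "RegionSet",
    "CLASS_I_REGIONS",
    "CLASS_II_REGIONS",
    "default_regions",
    "read_pdb",
    "pair_residues",
    "superpose",
    "weighted_rmsd",
    "coordinate_rmsd",
    "revised_rmsd",
]


@dataclass(frozen=True)
class RegionSet:
    """Inclusive residue-number intervals defining a scoring region."""

    hla_class: str  # "I" or "II"
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"interval ({start}, {end}) has start > end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    def __contains__(self, residue_number: int) -> bool:
        return any(s <= residue_number <= e for s, e in self.ranges)

    @property
    def n_positions(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


CLASS_I_REGIONS = RegionSet(
    "I", ((3, 13), (20, 38), (45, 85), (92, 103), (109, 127), (132, 178))
)
CLASS_II_REGIONS = RegionSet(
    "II", ((9, 18), (21, 30), (33, 39), (42, 47), (50, 87))
)


def default_regions(hla_class: str) -> RegionSet:
    if hla_class == "I":
        return CLASS_I_REGIONS
    if hla_class == "II":
        return CLASS_II_REGIONS
    raise ValueError(f"unknown HLA class {hla_class!r}")


def load_region_overrides(path: str | Path) -> dict[str, RegionSet]:
    """Read class -> [[start, end], ...] overrides from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return {
        cls: RegionSet(cls, tuple((int(s), int(e)) for s, e in ranges))
        for cls, ranges in raw.items()
    }


@dataclass(frozen=True)
class StructureModel:
    """Ordered Cα trace of one allele's modeled chain.

    ``residue_numbers`` are mature-protein 1-based, strictly increasing
    (gaps allowed); ``coords`` is the matching (n, 3) array in Å.
    """

    allele: Allele | None
    residue_numbers: tuple[int, ...]
    coords: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_numbers) != len(coords):
            raise ValueError("residue_numbers and coords disagree in length")
        nums = np.asarray(self.residue_numbers)
        if len(nums) < 3:
            raise ValueError("a structure model needs at least 3 residues")
        if np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)


def read_pdb(
    path: str | Path,
    allele: Allele | None = None,
    chain: str | None = None,
    atom: str = "CA",
    numbering_offset: int = 0,
) -> StructureModel:
    """Load one chain's per-residue trace from a PDB (or mmCIF) file.

    Parameters
    ----------
    chain
        Chain id to select; default is the first chain of the first model.
    atom
        Atom name to take per residue (default Cα).
    numbering_offset
        Added to the file's residue numbers to obtain mature-protein
        numbering (use a negative offset for files numbered with the
        leader peptide included).
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in structure file")
    model = structure[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError(f"{path}: no chains in first model")
        sel = model[0]
    else:
        sel = model.find_chain(chain)
        if sel is None:
            raise ValueError(f"{path}: chain {chain!r} not found")
    numbers: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    for residue in sel:
        ca = residue.find_atom(atom, "*")
        if ca is None:
            continue
        numbers.append(residue.seqid.num + numbering_offset)
        xyz.append((ca.pos.x, ca.pos.y, ca.pos.z))
    return StructureModel(
        allele=allele,
        residue_numbers=tuple(numbers),
        coords=np.asarray(xyz, dtype=float),
        source=f"{path}:{sel.name}",
    )


def pair_residues(
    m1: StructureModel,
    m2: StructureModel,
    region: RegionSet | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Match residues of two models by residue number.

    Residues absent from either model are dropped; with a ``region``,
    only residue numbers inside it are kept.  Returns ``(x, y, n)`` where
    x and y are (n, 3) coordinate arrays in matching order.
    """
    common = sorted(set(m1.residue_numbers) & set(m2.residue_numbers))
    if region is not None:
        common = [num for num in common if num in region]
    if len(common) < 3:
        where = "within region" if region is not None else "overall"
        raise ValueError(
            f"models share only {len(common)} residues {where}; need >= 3"
        )
    idx1 = {num: i for i, num in enumerate(m1.residue_numbers)}
    idx2 = {num: i for i, num in enumerate(m2.residue_numbers)}
    x = m1.coords[[idx1[num] for num in common]]
    y = m2.coords[[idx2[num] for num in common]]
    return x, y, len(common)


def _weights(weights: Sequence[float] | None, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weight sum must be positive")
    return w


def superpose(
    x: np.ndarray,
    y: np.ndarray,
    weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Kabsch: rotation R and translation t minimising
    sum_i w_i |x_i - (R y_i + t)|^2, with det(R) = +1.

    Raises on degenerate (collinear or coincident) configurations, where
    the rotation is not uniquely determined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("x and y must be matching (n, 3) arrays")
    if len(x) < 3:
        raise ValueError("superposition needs at least 3 point pairs")
    w = _weights(weights, len(x))
    wn = w / w.sum()
    xc = x - wn @ x
    yc = y - wn @ y
    cov = (yc * wn[:, None]).T @ xc
    u, s, vt = np.linalg.svd(cov)
    # Collinear (rank <= 1) configurations leave a free rotation axis.
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError(
            "degenerate configuration: points are collinear or coincident, "
            "rotation is not uniquely determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = (wn @ x) - rotation @ (wn @ y)
    return rotation, translation


def weighted_rmsd(
    x: np.ndarray,
    y: np.ndarray,
    weights: Sequence[float] | None = None,
) -> float:
    """sqrt(sum w_i |x_i - y_i|^2 / sum w_i); no superposition applied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate arrays must have matching shapes")
    if len(x) < 1:
        raise ValueError("need at least one coordinate pair")
    w = _weights(weights, len(x))
    sq = np.sum((x - y) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * sq) / np.sum(w)))


def _superposed_rmsd(
    m1: StructureModel,
    m2: StructureModel,
    region: RegionSet | None,
    weights: Sequence[float] | None,
    fit: str,
) -> float:
    if fit not in ("region", "all"):
        raise ValueError("fit must be 'region' or 'all'")
    x, y, _ = pair_residues(m1, m2, region)
    if fit == "all" and region is not None:
        xf, yf, _ = pair_residues(m1, m2, None)
        rotation, translation = superpose(xf, yf)
    else:
        rotation, translation = superpose(x, y, weights)
    y_fit = y @ rotation.T + translation
    return weighted_rmsd(x, y_fit, weights)


def coordinate_rmsd(
    m1: StructureModel,
    m2: StructureModel,
    weights: Sequence[float] | None = None,
) -> float:
    """RMSD over all common residues after optimal superposition (Å)."""
    return _superposed_rmsd(m1, m2, None, weights, fit="region")


def revised_rmsd(
    m1: StructureModel,
    m2: StructureModel,
    region: RegionSet | None = None,
    weights: Sequence[float] | None = None,
    fit: str = "region",
) -> float:
    """RMSD restricted to the functional recognition region (Å).

    ``region`` defaults to the class-specific recognition region of
    ``m1.allele``; ``fit="region"`` (default) superposes on the region
    residues themselves, ``fit="all"`` superposes on all common residues
    but scores only the region.
    """
    if region is None:
        if m1.allele is None:
            raise ValueError("no region given and model carries no allele")
        region = default_regions(m1.allele.hla_class)
    return _superposed_rmsd(m1, m2, region, weights, fit=fit)
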