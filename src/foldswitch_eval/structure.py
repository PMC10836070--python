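"""Structural models, Kabsch superposition, and dual-reference RMSD.

A predicted model of a fold-switching protein is scored against *both*
experimentally determined conformations over the fold-switching region: the
model is superposed independently onto each reference (least-squares rigid
superposition, proper rotations only) and the two RMSDs, together with the
region's mean plDDT, drive the downstream classification.

plDDT convention: AF2/ColabFold write per-residue confidence (0-100) into
the PDB B-factor column; values on a 0-1 scale are auto-detected (all
values <= 1.5) and rescaled by 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: threshold below which B-factors are interpreted as fractional plDDT
PLDDT_FRACTION_CUTOFF = 1.5


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: dict[str, np.ndarray]  # atom name -> xyz (Angstrom)

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code if code not in ("", " ") else "X"


@dataclass
class StructureModel:
    """One chain of heavy atoms with residue numbering and per-residue plDDT."""

    residues: list[Residue]
    per_residue_plddt: np.ndarray
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        self.per_residue_plddt = np.asarray(self.per_residue_plddt, dtype=float)
        if len(self.residues) != len(self.per_residue_plddt):
            raise ValidationError("one plDDT value per residue required")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValidationError("residue numbers must be strictly increasing")
        for r in self.residues:
            if "CA" not in r.atoms:
                raise ValidationError(f"residue {r.number} has no CA atom")
        if len(self.per_residue_plddt) and (
            self.per_residue_plddt.min() < 0 or self.per_residue_plddt.max() > 100
        ):
            raise ValidationError("plDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])


@dataclass
class ReferencePair:
    """The two experimentally determined conformations plus the
    fold-switching residue range (inclusive, 1-based)."""

    ground: StructureModel
    alternative: StructureModel
    region: tuple[int, int]
    labels: tuple[str, str] = ("ground state", "fold-switched")

    def __post_init__(self) -> None:
        a, b = self.region
        if b < a:
            raise ValidationError("region end precedes region start")
        seqs = []
        for m in (self.ground, self.alternative):
            present = {r.number: r for r in m.residues}
            missing = [n for n in range(a, b + 1) if n not in present]
            if missing:
                raise ValidationError(
                    f"region residues missing from a reference: {missing[:5]}"
                )
            seqs.append("".join(present[n].one_letter for n in range(a, b + 1)))
        if seqs[0] != seqs[1]:
            raise ValidationError(
                "references disagree in sequence over the fold-switching region"
            )


@dataclass
class DualRMSD:
    """RMSDs of one model against both reference conformations (Angstrom)."""

    rmsd_ground: float
    rmsd_alt: float
    n_atoms: int
    atom_mode: str = "all_heavy"

    def __post_init__(self) -> None:
        if self.rmsd_ground < 0 or self.rmsd_alt < 0:
            raise ValidationError("RMSDs must be non-negative")
        if self.n_atoms < 3:
            raise ValidationError("fewer than 3 matched atoms")


def read_model(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    First model only; altlocs other than blank/'A' discarded; hydrogens
    dropped; residues without a CA dropped with a warning.  The CA B-factor
    is taken as the residue's plDDT, rescaled from the 0-1 convention when
    all values are <= 1.5.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"{path}: no models found") from None
    picked_chain = None
    for ch in model:
        if chain is None or ch.id == chain:
            picked_chain = ch
            break
    if picked_chain is None:
        raise FormatError(f"{path}: chain {chain!r} not found")

    residues: list[Residue] = []
    plddts: list[float] = []
    for res in picked_chain:
        if res.id[0] != " ":  # skip HETATM / waters
            continue
        atoms: dict[str, np.ndarray] = {}
        ca_bfactor = None
        for atom in res.get_unpacked_list():
            if atom.get_altloc() not in (" ", "A"):
                continue
            if atom.element in ("H", "D"):
                continue
            atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atom.get_name() == "CA":
                ca_bfactor = float(atom.get_bfactor())
        if "CA" not in atoms:
            logger.warning(
                "%s: residue %s %s has no CA atom; dropped",
                path.name, res.get_resname(), res.id[1],
            )
            continue
        residues.append(Residue(number=res.id[1], name=res.get_resname(), atoms=atoms))
        plddts.append(ca_bfactor if ca_bfactor is not None else 0.0)
    if not residues:
        raise FormatError(f"{path}: no ATOM records with CA atoms")
    plddt = np.array(plddts, dtype=float)
    if plddt.max() <= PLDDT_FRACTION_CUTOFF:
        plddt = plddt * 100.0
    return StructureModel(
        residues=residues,
        per_residue_plddt=plddt,
        chain_id=picked_chain.id,
        source=str(path),
    )


def extract_region(m: StructureModel, interval: tuple[int, int]) -> StructureModel:
    """Residues whose numbers fall in the inclusive interval, order kept."""
    a, b = interval
    keep = [i for i, r in enumerate(m.residues) if a <= r.number <= b]
    if not keep:
        raise ParameterError(
            f"interval [{a}, {b}] selects no residues of {m.source or 'model'}"
        )
    return StructureModel(
        residues=[m.residues[i] for i in keep],
        per_residue_plddt=m.per_residue_plddt[keep],
        chain_id=m.chain_id,
        source=m.source,
    )


def mean_plddt(m: StructureModel, interval: tuple[int, int] | None = None) -> float:
    """Unweighted mean per-residue plDDT over an interval (or the whole chain)."""
    sub = m if interval is None else extract_region(m, interval)
    return float(sub.per_residue_plddt.mean())


def _pair_residues(a: StructureModel, b: StructureModel) -> list[tuple[int, int]]:
    """Indices of corresponding residues, by one-letter sequence alignment.

    Identical sequences pair positionally; otherwise a global alignment
    pairs residues and a warning is emitted when identity < 100% (mutant
    evaluation proceeds on matched atom names).
    """
    if a.sequence == b.sequence:
        return list(zip(range(len(a)), range(len(a))))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(a.sequence, b.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    mismatches = sum(1 for i, j in pairs if a.sequence[i] != b.sequence[j])
    if mismatches:
        logger.warning(
            "paired residues are not 100%% identical (%d mismatches); "
            "proceeding on matched atom names", mismatches,
        )
    return pairs


def map_atoms(
    a: StructureModel, b: StructureModel, atom_mode: str = "all_heavy"
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Paired coordinate arrays for two models of the same region.

    Residues are paired by sequence; within a residue pair, atoms are
    matched by name — ``all_heavy`` uses every non-hydrogen atom present in
    both, ``ca_only`` uses CA alone.  Returns two N x 3 arrays in identical
    order and the (residue number in a, atom name) label of each row.
    """
    if atom_mode not in ("all_heavy", "ca_only"):
        raise ParameterError(f"unknown atom_mode {atom_mode!r}")
    xs, ys, labels = [], [], []
    for i, j in _pair_residues(a, b):
        ra, rb = a.residues[i], b.residues[j]
        if atom_mode == "ca_only":
            names = ["CA"]
        else:
            names = sorted(set(ra.atoms) & set(rb.atoms))
        for name in names:
            xs.append(ra.atoms[name])
            ys.append(rb.atoms[name])
            labels.append((ra.number, name))
    if len(xs) < 3:
        raise ValidationError(f"only {len(xs)} matched atoms; need >= 3")
    return np.array(xs), np.array(ys), labels


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y (Kabsch algorithm).

    Returns (rotation R, translation t, rmsd) with det(R) = +1 — reflections
    are never allowed — such that R @ x + t approximates y and the RMSD is
    minimal over all proper rigid motions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ParameterError("X and Y must be matching N x 3 arrays")
    n = X.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 points")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - cx, Y - cy
    for M in (Xc, Yc):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= 1e-8 * max(1.0, s[0]):
            raise ParameterError("degenerate (collinear) point configuration")
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cy - R @ cx
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def dual_rmsd(
    model: StructureModel,
    refs: ReferencePair,
    atom_mode: str = "all_heavy",
    fit: str = "region",
) -> DualRMSD:
    """RMSD of the model's fold-switching region against both references.

    ``fit="region"`` (default) superposes on the region's atoms only;
    ``fit="whole"`` superposes on all shared atoms and then scores the
    region without re-fitting.
    """
    if fit not in ("region", "whole"):
        raise ParameterError(f"unknown fit mode {fit!r}")
    a, b = refs.region
    rmsds = []
    n_atoms = None
    for ref in (refs.ground, refs.alternative):
        if fit == "region":
            X, Y, labels = map_atoms(
                extract_region(model, refs.region),
                extract_region(ref, refs.region),
                atom_mode,
            )
            _, _, rmsd = kabsch_superpose(X, Y)
        else:
            X, Y, labels = map_atoms(model, ref, atom_mode)
            R, t, _ = kabsch_superpose(X, Y)
            mask = np.array([a <= num <= b for num, _name in labels])
            if mask.sum() < 3:
                raise ValidationError("fewer than 3 matched atoms in region")
            diff = (X[mask] @ R.T + t) - Y[mask]
            rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
            labels = [lab for lab, m in zip(labels, mask) if m]
        rmsds.append(rmsd)
        n_atoms = len(labels) if n_atoms is None else min(n_atoms, len(labels))
    return DualRMSD(
        rmsd_ground=rmsds[0],
        rmsd_alt=rmsds[1],
        n_atoms=int(n_atoms),
        atom_mode=atom_mode,
    )
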