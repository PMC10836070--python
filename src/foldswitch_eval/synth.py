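"""Synthetic inputs with known ground truth.

Everything the evaluation pipeline consumes can be generated here without
any structure-prediction software: toy two-conformation reference pairs
built from backbone internal coordinates, decoy model ensembles at
controlled RMSD and plDDT (stand-ins for predictor output), hybrid
conformers that match neither reference, and two-subfamily MSAs for the
clustering/subsampling stages.

Decoys are backbone-only (N, CA, C, O) — side chains add nothing to the
logic under test.  Perturbation is i.i.d. Gaussian per coordinate with
sigma = target_rmsd / sqrt(3), from E[RMSD^2] = 3 sigma^2; the small
shrinkage introduced by re-superposition is absorbed by the calibration
tolerance.  All randomness is seeded; no global state.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBIO, StructureBuilder

from .errors import ParameterError, ValidationError
from .msa import AMINO_ACIDS, Alignment
from .structure import (
    ReferencePair,
    Residue,
    StructureModel,
    dual_rmsd,
    extract_region,
    kabsch_superpose,
    map_atoms,
)

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)

#: minimum region RMSD between the two reference conformers at construction
MIN_REFERENCE_SEPARATION = 5.0


@dataclass
class DecoySpec:
    """One synthetic model: which conformer it is based on, how far from it
    (Å), and its plDDT profile (constant or per-residue)."""

    base: str  # ground | alternative | hybrid
    target_rmsd: float = 0.0
    plddt_profile: float | list[float] = 90.0
    seed: int = 0
    hybrid_split: int | None = None  # residue number starting the alt part

    def __post_init__(self) -> None:
        if self.base not in ("ground", "alternative", "hybrid"):
            raise ParameterError(f"unknown decoy base {self.base!r}")
        if self.target_rmsd < 0:
            raise ParameterError("target_rmsd must be >= 0")
        if self.base == "hybrid" and self.hybrid_split is None:
            raise ParameterError("hybrid decoys need hybrid_split")


@dataclass
class MsaSpec:
    """Two-subfamily MSA: two founders differing at a fraction
    ``founder_divergence`` of positions, each subfamily member mutating each
    position independently with probability ``mutation_rate``."""

    n_per_subfamily: int
    length: int
    founder_divergence: float = 0.6
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subfamily < 1:
            raise ParameterError("n_per_subfamily must be >= 1")
        if self.length < 1:
            raise ParameterError("length must be >= 1")
        for name in ("founder_divergence", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom d from three predecessors by internal coordinates (NeRF):
    |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) = torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_chain(
    sequence: str,
    phi: float | np.ndarray,
    psi: float | np.ndarray,
    plddt: float | np.ndarray = 100.0,
    chain_id: str = "A",
) -> StructureModel:
    """Backbone (N, CA, C, O) built by sequential internal-coordinate
    construction with ideal bond lengths/angles and trans peptide bonds.

    ``phi``/``psi`` are degrees, scalar or per-residue; residues are
    numbered 1..L.
    """
    L = len(sequence)
    if L < 4:
        raise ParameterError("chain needs at least 4 residues")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ParameterError(f"unknown residue letters: {sorted(bad)}")
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (L,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (L,))

    N = [np.zeros(3)]
    ang = math.radians(ANGLE_N_CA_C)
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    O: list[np.ndarray] = []
    for i in range(1, L):
        N.append(_place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1]))
        CA.append(_place_atom(CA[-1], C[-1], N[-1], BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(_place_atom(C[-1], N[-1], CA[-1], BOND_CA_C, ANGLE_N_CA_C, phi[i]))
        O.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_O, ANGLE_CA_C_O,
                             psi[i - 1] + 180.0))
    # last carbonyl oxygen: same construction, psi of the final residue
    O.append(_place_atom(N[-1], CA[-1], C[-1], BOND_C_O, ANGLE_CA_C_O,
                         psi[-1] + 180.0))

    residues = []
    for i, aa in enumerate(sequence):
        residues.append(Residue(
            number=i + 1,
            name=protein_letters_1to3[aa].upper(),
            atoms={"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]},
        ))
    plddt_arr = np.broadcast_to(np.asarray(plddt, dtype=float), (L,)).copy()
    return StructureModel(
        residues=residues, per_residue_plddt=plddt_arr,
        chain_id=chain_id, source="synthetic",
    )


def make_fold_pair(
    length: int = 60,
    region: tuple[int, int] | None = None,
    seed: int = 0,
    ground_dihedrals: tuple[float, float] = HELIX,
    alt_dihedrals: tuple[float, float] = STRAND,
) -> ReferencePair:
    """A toy fold-switching protein: the same sequence built twice, helical
    over the region in the ground state and extended in the alternative
    state (flanks identical).  Construction fails unless the two conformers
    are separated by more than 5 Å RMSD over the region."""
    if length < 20:
        raise ParameterError("need length >= 20")
    if region is None:
        region = (1, length)
    a, b = region
    if not (1 <= a <= b <= length):
        raise ParameterError(f"region {region} outside chain 1..{length}")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))

    def dihedral_arrays(pair: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        phi = np.full(length, HELIX[0])
        psi = np.full(length, HELIX[1])
        phi[a - 1 : b] = pair[0]
        psi[a - 1 : b] = pair[1]
        return phi, psi

    ground = build_chain(sequence, *dihedral_arrays(ground_dihedrals))
    alt = build_chain(sequence, *dihedral_arrays(alt_dihedrals))
    pair = ReferencePair(ground=ground, alternative=alt, region=region)
    X, Y, _ = map_atoms(
        extract_region(ground, region), extract_region(alt, region)
    )
    _, _, separation = kabsch_superpose(X, Y)
    if separation <= MIN_REFERENCE_SEPARATION:
        raise ValidationError(
            f"reference conformers are not separable: region RMSD "
            f"{separation:.2f} Å <= {MIN_REFERENCE_SEPARATION} Å"
        )
    return pair


def _splice_hybrid(refs: ReferencePair, split: int) -> StructureModel:
    """Ground-state coordinates before ``split`` joined to alternative-state
    coordinates from ``split`` on, the alternative part rigidly aligned onto
    the ground frame at a 3-residue junction window."""
    numbers = refs.ground.numbers
    if split not in numbers or split == numbers[0]:
        raise ParameterError(f"hybrid_split {split} not inside the chain")
    window = [n for n in (split - 1, split, split + 1) if n in numbers]
    gw = extract_region(refs.ground, (window[0], window[-1]))
    aw = extract_region(refs.alternative, (window[0], window[-1]))
    X, Y, _ = map_atoms(aw, gw)
    R, t, _ = kabsch_superpose(X, Y)
    residues = []
    for rg, ra in zip(refs.ground.residues, refs.alternative.residues):
        if rg.number < split:
            residues.append(copy.deepcopy(rg))
        else:
            atoms = {name: R @ xyz + t for name, xyz in ra.atoms.items()}
            residues.append(Residue(number=ra.number, name=ra.name, atoms=atoms))
    return StructureModel(
        residues=residues,
        per_residue_plddt=refs.ground.per_residue_plddt.copy(),
        chain_id=refs.ground.chain_id,
        source="synthetic-hybrid",
    )


def make_decoy(refs: ReferencePair, spec: DecoySpec) -> StructureModel:
    """A decoy model: the chosen base conformer perturbed by zero-mean
    Gaussian coordinate noise with sigma = target_rmsd / sqrt(3), plDDT
    written from the profile.  Deterministic per seed."""
    if spec.base == "ground":
        base = refs.ground
    elif spec.base == "alternative":
        base = refs.alternative
    else:
        base = _splice_hybrid(refs, spec.hybrid_split)
    rng = np.random.default_rng(spec.seed)
    sigma = spec.target_rmsd / math.sqrt(3.0)
    residues = []
    for r in base.residues:
        atoms = {
            name: xyz + rng.normal(0.0, sigma, size=3) if sigma > 0 else xyz.copy()
            for name, xyz in r.atoms.items()
        }
        residues.append(Residue(number=r.number, name=r.name, atoms=atoms))
    L = len(residues)
    plddt = np.broadcast_to(
        np.asarray(spec.plddt_profile, dtype=float), (L,)
    ).copy()
    return StructureModel(
        residues=residues, per_residue_plddt=plddt,
        chain_id=base.chain_id, source=f"synthetic-decoy-{spec.base}",
    )


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a model as a single-chain PDB file, per-residue plDDT in the
    B-factor column of every atom (the AF2/ColabFold convention)."""
    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("model")
    sb.init_model(0)
    sb.init_chain(model.chain_id)
    sb.init_seg("    ")
    serial = 1
    for res, plddt in zip(model.residues, model.per_residue_plddt):
        sb.init_residue(res.name, " ", res.number, " ")
        for name, xyz in res.atoms.items():
            fullname = name.center(4) if len(name) < 4 else name
            sb.init_atom(
                name, np.asarray(xyz, dtype=float), float(plddt), 1.0, " ",
                fullname, serial, element=name[0],
            )
            serial += 1
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def make_ensemble(
    refs: ReferencePair,
    specs: list[DecoySpec],
    outdir: str | Path,
    run_ids: list[str] | None = None,
) -> dict:
    """Write one PDB per spec plus a JSON truth manifest of generator labels.

    The manifest records each model's file name, base conformer, target
    RMSD, plDDT summary, seed, and optional run id; it round-trips through
    the evaluation pipeline's reader.
    """
    if not specs:
        raise ParameterError("empty spec list")
    if run_ids is not None and len(run_ids) != len(specs):
        raise ParameterError("need one run id per spec")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"region": list(refs.region), "models": []}
    for i, spec in enumerate(specs):
        model = make_decoy(refs, spec)
        fname = f"model_{i:03d}.pdb"
        write_model(model, outdir / fname)
        entry = {
            "file": fname,
            "base": spec.base,
            "target_rmsd": spec.target_rmsd,
            "plddt": (
                spec.plddt_profile
                if isinstance(spec.plddt_profile, (int, float))
                else list(map(float, spec.plddt_profile))
            ),
            "seed": spec.seed,
        }
        if spec.hybrid_split is not None:
            entry["hybrid_split"] = spec.hybrid_split
        if run_ids is not None:
            entry["run_id"] = run_ids[i]
        manifest["models"].append(entry)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def synth_msa(spec: MsaSpec) -> tuple[Alignment, np.ndarray]:
    """Two-subfamily MSA with known membership.

    Two founder sequences differ at ``ceil(founder_divergence * length)``
    positions; every member mutates each position with probability
    ``mutation_rate`` to a uniformly chosen different residue.  Founder A
    itself is prepended as the query.  Returns the alignment and the
    per-row subfamily labels (0 = A, including the query; 1 = B).
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    founder_a = rng.choice(letters, size=spec.length)
    founder_b = founder_a.copy()
    n_div = math.ceil(spec.founder_divergence * spec.length)
    div_pos = rng.choice(spec.length, size=n_div, replace=False)
    for p in div_pos:
        choices = letters[letters != founder_a[p]]
        founder_b[p] = rng.choice(choices)

    ids = ["query"]
    rows = ["".join(founder_a)]
    labels = [0]
    for fam, founder in (("A", founder_a), ("B", founder_b)):
        for j in range(spec.n_per_subfamily):
            member = founder.copy()
            mutate = rng.random(spec.length) < spec.mutation_rate
            for p in np.nonzero(mutate)[0]:
                choices = letters[letters != member[p]]
                member[p] = rng.choice(choices)
            ids.append(f"{fam}_{j:04d}")
            rows.append("".join(member))
            labels.append(0 if fam == "A" else 1)
    return Alignment(ids=ids, rows=rows, query_index=0), np.array(labels)
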