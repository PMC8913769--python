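"""Seeded generators for molecules and labelled datasets with known truth.

These stand in for the external benchmark collections (conformer ensembles
with high-level reference energies, solvation free-energy compilations,
inhibitor/non-inhibitor screens), which cannot ship with the package.  Every
generator is a pure function of its spec — seed included — so outputs are
byte-identical across runs, and the recorded ground truth (designated
feature columns, weights, noise level) suffices to compute the Bayes-optimal
error each learning protocol should approach.

What is emulated: per-medium energy attributes with polarity/dielectric
structure (via the mock engine), conformer groups sharing one parent
geometry, targets that are known linear maps of designated feature columns
plus noise.  What is not: real electronic structure, realistic conformer
ensembles, chemistry-driven class boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_io import ConformerGroup, Molecule, write_groups_csv, write_structures
from .engines import Medium, MockEngine, default_media_panel, run_media_panel
from .featurize import FeatureMatrix, assemble

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "gen_molecules",
    "gen_conformer_dataset",
    "gen_solvation_dataset",
    "gen_classification_dataset",
]

_ELEMENT_POOL = ("H", "C", "N", "O", "F", "S")

# Default ground-truth columns per preset: smooth geometry-sensitive
# attributes that vary between conformers of one group (electrostatic and
# cavitation solvation terms; weights sized so conformer energy spreads land
# at a realistic few kcal/mol) for regression; partitioning-like solvation
# columns (water/octanol free energies) for classification.
_CONFORMER_TRUE = {"water|8": 2.0, "water|9": 5.0, "acetone|8": 1.5}
_CLASSIFICATION_TRUE = {"water|7": 1.0, "octanol|7": -1.2, "vacuum|3": 0.8}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset; the seed is part of the identity."""

    preset: str  # conformers | solvation | classification
    n_groups: int = 100
    n_conformers: int = 5
    n_samples: int = 500
    noise_sigma: float = 0.5
    true_columns: list[str] = field(default_factory=list)
    true_weights: list[float] = field(default_factory=list)
    atoms_range: tuple[int, int] = (4, 8)
    charge_set: tuple[int, ...] = (0, 0, 0, 1, -1)
    jitter: float = 0.1  # conformer coordinate perturbation, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("conformers", "solvation", "classification"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.noise_sigma < 0 or not np.isfinite(self.noise_sigma):
            raise ValueError("noise_sigma must be finite and >= 0")
        if len(self.true_columns) != len(self.true_weights):
            raise ValueError("true_columns and true_weights must align")
        if not self.true_columns:
            defaults = (_CONFORMER_TRUE if self.preset != "classification"
                        else _CLASSIFICATION_TRUE)
            self.true_columns = list(defaults)
            self.true_weights = [defaults[c] for c in self.true_columns]


@dataclass
class SyntheticDataset:
    """Generated structures, features, targets and the recorded ground truth."""

    spec: SyntheticSpec
    molecules: list[Molecule]
    features: FeatureMatrix
    groups: list[ConformerGroup] | None
    target: np.ndarray | None  # continuous target (kcal/mol) or None
    labels: np.ndarray | None  # binary labels or None
    ground_truth: dict

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write structures (XYZ), features/targets/groups (CSV) and the
        ground-truth sidecar (JSON); returns the artifact paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts = {}
        write_structures(self.molecules, out / "structures.xyz")
        artifacts["structures"] = str(out / "structures.xyz")
        self.features.to_csv(out / "features.csv")
        artifacts["features"] = str(out / "features.csv")
        if self.groups is not None:
            write_groups_csv(self.groups, out / "groups.csv")
            artifacts["groups"] = str(out / "groups.csv")
        if self.target is not None:
            _write_target_csv(out / "target.csv", self.features.sample_ids,
                              self.target, "target")
            artifacts["target"] = str(out / "target.csv")
        if self.labels is not None:
            _write_target_csv(out / "labels.csv", self.features.sample_ids,
                              self.labels, "label")
            artifacts["labels"] = str(out / "labels.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True, default=float)
        )
        artifacts["ground_truth"] = str(out / "ground_truth.json")
        return artifacts


def _write_target_csv(path: Path, ids: Sequence[str], values: np.ndarray,
                      colname: str) -> None:
    lines = [f"sample_id,{colname}"]
    lines += [f"{s},{v}" for s, v in zip(ids, values)]
    path.write_text("\n".join(lines) + "\n")


def gen_molecules(
    n: int,
    atoms_range: tuple[int, int] = (4, 8),
    charge_set: Sequence[int] = (0,),
    seed: int = 0,
    id_prefix: str = "mol",
) -> list[Molecule]:
    """Random molecules: elements from H/C/N/O/F/S, coordinates in a box with
    a 0.8 Å minimum interatomic distance enforced by rejection sampling."""
    lo, hi = atoms_range
    if not 1 <= lo <= hi <= 50:
        raise ValueError("atoms_range must lie within [1, 50]")
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(n):
        n_atoms = int(rng.integers(lo, hi + 1))
        box = 1.5 * n_atoms ** (1 / 3) + 1.5  # roughly constant density
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            for attempt in range(500):
                cand = rng.uniform(0.0, box, size=3)
                if a == 0 or np.min(np.linalg.norm(coords[:a] - cand, axis=1)) >= 0.8:
                    coords[a] = cand
                    break
            else:
                raise RuntimeError(
                    f"could not place atom {a} after 500 attempts; "
                    "a larger box (fewer atoms) is needed"
                )
        elements = [str(rng.choice(_ELEMENT_POOL)) for _ in range(n_atoms)]
        charge = int(rng.choice(np.asarray(charge_set)))
        molecules.append(Molecule(f"{id_prefix}_{i}", elements, coords, charge))
    return molecules


def _panel_features(
    molecules: Sequence[Molecule],
    media: Sequence[Medium],
    group_of: dict[str, str] | None = None,
) -> FeatureMatrix:
    engine = MockEngine()
    panel = {m.id: run_media_panel(engine, m, media) for m in molecules}
    return assemble(panel, media, group_ids=group_of)


def _linear_truth(fm: FeatureMatrix, spec: SyntheticSpec) -> np.ndarray:
    cols = np.column_stack([fm.column(c) for c in spec.true_columns])
    return cols @ np.asarray(spec.true_weights)


def gen_conformer_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Groups of jittered conformers with a reference-quality surrogate target.

    Each group is one base molecule plus ``n_conformers - 1`` coordinate-
    jittered copies; the target is a known linear map over designated mock
    feature columns plus Gaussian noise, playing the role of a high-level
    reference energy.  Because the truth is linear in the features, delta
    correction of features and target preserves the same map exactly.
    """
    if spec.preset != "conformers":
        raise ValueError("spec.preset must be 'conformers'")
    rng = np.random.default_rng(spec.seed)
    bases = gen_molecules(
        spec.n_groups, spec.atoms_range, spec.charge_set,
        seed=int(rng.integers(0, 2**31 - 1)), id_prefix="base",
    )
    molecules: list[Molecule] = []
    groups: list[ConformerGroup] = []
    group_of: dict[str, str] = {}
    for g, base in enumerate(bases):
        gid = f"g{g:04d}"
        members = []
        for c in range(spec.n_conformers):
            coords = base.coordinates.copy()
            if c > 0:
                coords = coords + rng.normal(0.0, spec.jitter, size=coords.shape)
            mid = f"{gid}_c{c}"
            molecules.append(
                Molecule(mid, list(base.elements), coords, base.net_charge)
            )
            members.append(mid)
            group_of[mid] = gid
        groups.append(ConformerGroup(gid, members))

    media = default_media_panel()
    fm = _panel_features(molecules, media, group_of)
    signal = _linear_truth(fm, spec)
    noise = rng.normal(0.0, spec.noise_sigma, size=len(signal))
    target = signal + noise
    # conformer energies (vacuum total energy) for spanning-selection use
    e_vac = fm.column("vacuum|1")
    row_of = {s: i for i, s in enumerate(fm.sample_ids)}
    for g in groups:
        g.energies = [float(e_vac[row_of[m]]) for m in g.members]

    ground_truth = {
        "preset": "conformers",
        "true_columns": spec.true_columns,
        "true_weights": spec.true_weights,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "signal": signal.tolist(),
    }
    return SyntheticDataset(spec, molecules, fm, groups, target, None, ground_truth)


def gen_solvation_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Solute-solvent mixtures with a transfer-free-energy-like target.

    Each sample is one molecule assigned one of the nine solvents; the target
    combines the sample's own-solvent electrostatic and cavitation terms with
    a dielectric contribution, plus Gaussian noise — so the dielectric column
    and the solvation-component columns carry the signal.  No delta treatment
    applies in this mode.
    """
    if spec.preset != "solvation":
        raise ValueError("spec.preset must be 'solvation'")
    rng = np.random.default_rng(spec.seed)
    molecules = gen_molecules(
        spec.n_samples, spec.atoms_range, spec.charge_set,
        seed=int(rng.integers(0, 2**31 - 1)), id_prefix="solute",
    )
    media = default_media_panel()
    solvents = [m for m in media if not m.is_vacuum]
    assignment = {
        mol.id: solvents[int(rng.integers(0, len(solvents)))] for mol in molecules
    }
    fm = _panel_features(molecules, media)
    engine = MockEngine()
    own_g_elec = np.array(
        [engine.compute(mol, assignment[mol.id])["g_elec"] for mol in molecules]
    )
    own_g_cav = np.array(
        [engine.compute(mol, assignment[mol.id])["g_cav"] for mol in molecules]
    )
    eps = np.array([assignment[mol.id].dielectric for mol in molecules])
    signal = own_g_elec + own_g_cav - 0.05 * eps
    target = signal + rng.normal(0.0, spec.noise_sigma, size=len(signal))
    ground_truth = {
        "preset": "solvation",
        "truth": "own-solvent g_elec + g_cav - 0.05*eps",
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "solvent_of_sample": {m.id: assignment[m.id].name for m in molecules},
        "signal": signal.tolist(),
    }
    ds = SyntheticDataset(spec, molecules, fm, None, target, None, ground_truth)
    ds.ground_truth["sample_solvent_eps"] = {m.id: assignment[m.id].dielectric
                                             for m in molecules}
    return ds


def gen_classification_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Binary inhibitor-like labels from a latent linear score.

    label = 1{score + logistic noise + intercept > 0} with the intercept set
    at the median latent value, which pins the class balance near one half
    (always inside the required [0.35, 0.65] band for continuous scores).
    """
    if spec.preset != "classification":
        raise ValueError("spec.preset must be 'classification'")
    rng = np.random.default_rng(spec.seed)
    molecules = gen_molecules(
        spec.n_samples, spec.atoms_range, spec.charge_set,
        seed=int(rng.integers(0, 2**31 - 1)), id_prefix="cand",
    )
    media = default_media_panel()
    fm = _panel_features(molecules, media)
    score = _linear_truth(fm, spec)
    score = (score - score.mean()) / (score.std() or 1.0)  # unit-scale latent
    noise = rng.logistic(0.0, spec.noise_sigma, size=len(score)) if spec.noise_sigma else np.zeros(len(score))
    latent = score + noise
    intercept = -float(np.median(latent))
    labels = (latent + intercept > 0).astype(int)
    balance = float(labels.mean())
    if not 0.35 <= balance <= 0.65:
        raise RuntimeError(f"class balance {balance:.2f} outside [0.35, 0.65]")
    ground_truth = {
        "preset": "classification",
        "true_columns": spec.true_columns,
        "true_weights": spec.true_weights,
        "noise_scale": spec.noise_sigma,
        "intercept": intercept,
        "seed": spec.seed,
        "balance": balance,
        "score": score.tolist(),
    }
    return SyntheticDataset(spec, molecules, fm, None, None, labels, ground_truth)
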