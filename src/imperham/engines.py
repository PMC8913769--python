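"""Per-(molecule, medium) energy attributes: contract, mock engine, xtb adapter.

A *medium* is vacuum or a named continuum solvent with a dielectric constant;
perturbing the solute Hamiltonian by the medium (the ALPB implicit-solvation
model in the external engine, a documented closed-form surrogate in the mock
engine) yields 18 scalar energy attributes per molecule and medium.  These
attributes — total and SCC energies, frontier-orbital eigenvalues, the
solvation free-energy decomposition, dispersion/repulsion terms — are the raw
material of the representation pool.

Units: energies kcal/mol, orbital quantities eV, gradient norm kcal/mol/Å.
External engine output in Hartree is converted at parse time.
"""

from __future__ import annotations

import dataclasses
import re
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_io import Molecule, write_structures

__all__ = [
    "HARTREE_TO_KCAL",
    "Medium",
    "EnergyAttributes",
    "ATTRIBUTE_IDS",
    "ATTRIBUTE_NAMES",
    "MockParams",
    "MockEngine",
    "mock_attributes",
    "XtbEngine",
    "EngineUnavailableError",
    "EngineParseError",
    "MediaPanelError",
    "default_media_panel",
    "load_media_panel",
    "run_media_panel",
]

HARTREE_TO_KCAL = 627.509474
HARTREE_TO_EV = 27.211386245988

# Attribute ids are fixed 1..18 in this order; feature-column labels use the id.
ATTRIBUTE_NAMES: dict[int, str] = {
    1: "total_energy",
    2: "total_free_energy_no_cav_hb",
    3: "homo_lumo_gap",
    4: "homo_eigenvalue",
    5: "lumo_eigenvalue",
    6: "scc_energy",
    7: "g_total",
    8: "g_elec",
    9: "g_cav",
    10: "g_hb",
    11: "g_shift_inf_dilution",
    12: "gradient_norm",
    13: "isotropic_es",
    14: "anisotropic_xc",
    15: "isotropic_xc",
    16: "dispersion_energy",
    17: "repulsion_energy",
    18: "atomization_energy",
}
ATTRIBUTE_IDS: dict[str, int] = {v: k for k, v in ATTRIBUTE_NAMES.items()}

_SOLVATION_FIELDS = ("g_total", "g_elec", "g_cav", "g_hb", "g_shift_inf_dilution")


@dataclass(frozen=True)
class Medium:
    """Vacuum or a named implicit solvent.

    ``dielectric`` >= 1 with vacuum exactly 1; ``engine_key`` is the solvent
    keyword the external engine understands (empty for vacuum); ``hb_strength``
    in [0, 1] is the mock engine's hydrogen-bond propensity and is ignored by
    the external adapter.
    """

    name: str
    dielectric: float
    engine_key: str = ""
    hb_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.dielectric < 1.0:
            raise ValueError(f"medium {self.name!r}: dielectric must be >= 1")
        if not 0.0 <= self.hb_strength <= 1.0:
            raise ValueError(f"medium {self.name!r}: hb_strength must be in [0,1]")

    @property
    def is_vacuum(self) -> bool:
        return self.dielectric == 1.0


@dataclass(frozen=True)
class EnergyAttributes:
    """The 18 energy components for one (molecule, medium) pair."""

    total_energy: float
    total_free_energy_no_cav_hb: float
    homo_lumo_gap: float
    homo_eigenvalue: float
    lumo_eigenvalue: float
    scc_energy: float
    g_total: float
    g_elec: float
    g_cav: float
    g_hb: float
    g_shift_inf_dilution: float
    gradient_norm: float
    isotropic_es: float
    anisotropic_xc: float
    isotropic_xc: float
    dispersion_energy: float
    repulsion_energy: float
    atomization_energy: float

    def __post_init__(self) -> None:
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("energy attributes must all be finite")
        gap_residual = self.homo_lumo_gap - (self.lumo_eigenvalue - self.homo_eigenvalue)
        if abs(gap_residual) > 1e-6:
            raise ValueError(
                f"gap inconsistency: gap - (lumo - homo) = {gap_residual:g} eV"
            )

    def as_vector(self) -> np.ndarray:
        """Attribute values ordered by id 1..18."""
        return np.array(
            [getattr(self, ATTRIBUTE_NAMES[i]) for i in range(1, 19)], dtype=float
        )

    def __getitem__(self, key: int | str) -> float:
        name = ATTRIBUTE_NAMES[key] if isinstance(key, int) else key
        return float(getattr(self, name))


class EngineUnavailableError(RuntimeError):
    """External engine missing or exited nonzero; carries the captured log."""

    def __init__(self, message: str, log: str = "") -> None:
        super().__init__(message)
        self.log = log


class EngineParseError(ValueError):
    """An expected attribute could not be parsed from engine output."""


# ---------------------------------------------------------------------------
# Default media panel: vacuum + the nine named solvents.  Dielectric constants
# are standard 25 degC values from physical-chemistry tables, shipped as
# config defaults (override per run); hb_strength is a mock-engine knob.
# ---------------------------------------------------------------------------

_DEFAULT_PANEL: tuple[tuple[str, float, str, float], ...] = (
    ("vacuum", 1.0, "", 0.0),
    ("acetone", 20.7, "acetone", 0.3),
    ("acetonitrile", 37.5, "acetonitrile", 0.3),
    ("benzene", 2.27, "benzene", 0.0),
    ("hexane", 1.88, "hexane", 0.0),
    ("water", 80.1, "water", 1.0),
    ("ether", 4.27, "ether", 0.2),
    ("ethylacetate", 6.02, "ethylacetate", 0.3),
    ("octanol", 9.86, "octanol", 0.6),
    ("phenol", 8.0, "phenol", 0.8),
)


def default_media_panel() -> list[Medium]:
    """Vacuum plus the nine-solvent panel spanning dielectrics ~1.9 to ~80."""
    return [Medium(n, eps, key, hb) for n, eps, key, hb in _DEFAULT_PANEL]


def load_media_panel(path: str | Path) -> list[Medium]:
    """Read a media panel from YAML: a list of mappings with keys
    ``name``, ``dielectric`` and optional ``engine_key``/``hb_strength``."""
    import yaml

    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: expected a YAML list of media")
    return [
        Medium(
            name=e["name"],
            dielectric=float(e["dielectric"]),
            engine_key=e.get("engine_key", ""),
            hb_strength=float(e.get("hb_strength", 0.0)),
        )
        for e in entries
    ]


# ---------------------------------------------------------------------------
# Mock engine: documented closed forms of composition, geometry, charge, eps.
# ---------------------------------------------------------------------------

# Pseudo-charges for the mock dipole; roughly electronegativity-ordered,
# carbon as the zero reference.  Unlisted elements contribute 0.
_PSEUDO_CHARGES = {
    "H": 0.15, "C": 0.0, "N": -0.20, "O": -0.30, "F": -0.40,
    "S": -0.10, "Cl": -0.25, "P": 0.05, "Br": -0.20, "I": -0.15,
}


@dataclass(frozen=True)
class MockParams:
    """Constants of the mock closed forms (versioned defaults).

    k1 scales the Born-like electrostatic solvation term, k2 the dielectric
    response of the frontier-orbital gap (eV), k3 the hydrogen-bond term per
    N/O/F atom, k4 the infinite-dilution shift; a is the per-atom cohesive
    scale, b/c the exponential-repulsion and capped-dispersion prefactors,
    r0 a Born-radius offset (Å), gamma0/gamma1 the cavitation surface-tension
    intercept/slope against the dielectric constant.
    """

    k1: float = 20.0
    k2: float = 0.5
    k3: float = 2.0
    k4: float = 1.5
    a: float = 5.0
    b: float = 50.0
    c: float = 2.0
    r0: float = 1.0
    gamma0: float = 0.05
    gamma1: float = 0.02
    version: str = "1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MockParams":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _pairwise_terms(coords: np.ndarray, b: float, c: float) -> tuple[float, float, np.ndarray]:
    """Repulsion sum(b e^{-r}), capped dispersion -sum(c min(r,1)^-6), and the
    analytic gradient of their sum, per atom."""
    n = coords.shape[0]
    e_rep = 0.0
    e_disp = 0.0
    grad = np.zeros_like(coords)
    for i in range(n):
        for j in range(i + 1, n):
            dvec = coords[i] - coords[j]
            r = float(np.linalg.norm(dvec))
            e_rep += b * np.exp(-r)
            e_disp += -c * min(r, 1.0) ** -6
            # d/dr of b e^{-r} is -b e^{-r}; dispersion gradient vanishes for
            # r > 1 where the cap is active.
            dr = -b * np.exp(-r)
            if r < 1.0:
                dr += 6.0 * c * r**-7
            g = dr * dvec / r
            grad[i] += g
            grad[j] -= g
    return e_rep, e_disp, grad


class MockEngine:
    """Deterministic closed-form surrogate engine for offline pipelines.

    Emulates the qualitative structure of continuum-solvation energy
    decompositions — a Born-like electrostatic term growing with polarity and
    the dielectric factor f(eps) = 1 - 1/eps, a cavitation term growing with
    molecular size and eps, a hydrogen-bond term counting N/O/F acceptors —
    without any claim to physical accuracy.  Pure function of its inputs:
    bit-identical output across runs and platforms.
    """

    name = "mock"

    def __init__(self, params: MockParams | None = None) -> None:
        self.params = params or MockParams()

    def compute(self, molecule: Molecule, medium: Medium) -> EnergyAttributes:
        p = self.params
        eps = medium.dielectric
        if eps < 1.0:
            raise ValueError("dielectric must be >= 1")
        f = 1.0 - 1.0 / eps  # Born factor; 0 in vacuum
        coords = molecule.coordinates
        z = molecule.atomic_numbers()
        n = molecule.n_atoms
        z_sum = float(z.sum())

        centroid = coords.mean(axis=0)
        centered = coords - centroid
        q = np.array([_PSEUDO_CHARGES.get(e, 0.0) for e in molecule.elements])
        mu = float(np.linalg.norm(q @ centered))  # pseudo-polarity, e*Angstrom
        r_g = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
        n_nof = sum(1 for e in molecule.elements if e in ("N", "O", "F"))

        if medium.is_vacuum:
            g_elec = g_cav = g_hb = g_shift = 0.0
        else:
            g_elec = -p.k1 * f * (mu**2 + molecule.net_charge**2) / (r_g + p.r0)
            g_cav = (p.gamma0 + p.gamma1 * eps) * r_g**2
            g_hb = -p.k3 * f * medium.hb_strength * n_nof
            g_shift = p.k4
        g_total = g_elec + g_cav + g_hb + g_shift

        e_rep, e_disp, grad = _pairwise_terms(coords, p.b, p.c)
        e_atoms = float(np.sum(-p.a * z**1.2))
        total_energy = e_atoms + e_rep + e_disp + g_elec
        scc_energy = total_energy - e_rep
        gradient_norm = float(np.linalg.norm(grad))

        # Frontier orbitals: smooth in atom count, Z-sum and f(eps); the gap
        # stays positive for any molecule (2 + 8/(1+0.1n) > k2 >= k2*f).
        gap = 2.0 + 8.0 / (1.0 + 0.1 * n) - p.k2 * f
        homo = -(4.0 + 0.1 * z_sum / n + f)
        lumo = homo + gap

        # Remaining attributes: documented smooth combinations of the above.
        free_energy_total = total_energy + g_cav + g_hb + g_shift
        total_free_no_cav_hb = free_energy_total - g_cav - g_hb
        isotropic_es = 0.3 * g_elec - 0.02 * z_sum
        anisotropic_xc = -0.01 * z_sum**1.1 + 0.1 * f * n
        isotropic_xc = -0.03 * z_sum + 0.05 * r_g
        atomization = total_energy - e_atoms  # binding relative to free atoms

        return EnergyAttributes(
            total_energy=total_energy,
            total_free_energy_no_cav_hb=total_free_no_cav_hb,
            homo_lumo_gap=gap,
            homo_eigenvalue=homo,
            lumo_eigenvalue=lumo,
            scc_energy=scc_energy,
            g_total=g_total,
            g_elec=g_elec,
            g_cav=g_cav,
            g_hb=g_hb,
            g_shift_inf_dilution=g_shift,
            gradient_norm=gradient_norm,
            isotropic_es=isotropic_es,
            anisotropic_xc=anisotropic_xc,
            isotropic_xc=isotropic_xc,
            dispersion_energy=e_disp,
            repulsion_energy=e_rep,
            atomization_energy=atomization,
        )


def mock_attributes(
    molecule: Molecule, medium: Medium, params: MockParams | None = None
) -> EnergyAttributes:
    """Functional entry point to the mock closed forms."""
    return MockEngine(params).compute(molecule, medium)


# ---------------------------------------------------------------------------
# External engine adapter (GFN2-xTB with ALPB solvation).
# ---------------------------------------------------------------------------

# Pattern table mapping each attribute to a line in the engine's stdout.
# Kept in one versioned config so output drift across engine versions is a
# config fix.  Each value is (regex with one float group, unit) where unit is
# "hartree" (-> kcal/mol), "ev" (kept), or "hartree_per_bohr" (-> kcal/mol/A).
BOHR_TO_ANGSTROM = 0.529177210903

XTB_OUTPUT_PATTERNS: dict[str, tuple[str, str]] = {
    "total_energy": (r"::\s+total energy\s+(-?[\d.]+)\s+Eh", "hartree"),
    "free_energy": (r"::\s+total free energy\s+(-?[\d.]+)\s+Eh", "hartree"),
    "homo_lumo_gap": (r"::\s+HOMO-LUMO gap\s+(-?[\d.]+)\s+eV", "ev"),
    "homo_eigenvalue": (r"(-?[\d.]+)\s+\(HOMO\)", "ev"),
    "lumo_eigenvalue": (r"(-?[\d.]+)\s+\(LUMO\)", "ev"),
    "scc_energy": (r"::\s+SCC energy\s+(-?[\d.]+)\s+Eh", "hartree"),
    "g_total": (r"::\s+-> Gsolv\s+(-?[\d.]+)\s+Eh", "hartree"),
    "g_elec": (r"::\s+-> Gelec\s+(-?[\d.]+)\s+Eh", "hartree"),
    "g_cav": (r"::\s+-> Gsasa\s+(-?[\d.]+)\s+Eh", "hartree"),
    "g_hb": (r"::\s+-> Ghb\s+(-?[\d.]+)\s+Eh", "hartree"),
    "g_shift_inf_dilution": (r"::\s+-> Gshift\s+(-?[\d.]+)\s+Eh", "hartree"),
    "gradient_norm": (r"::\s+gradient norm\s+(-?[\d.]+)\s+Eh/a0", "hartree_per_bohr"),
    "isotropic_es": (r"::\s+-> isotropic ES\s+(-?[\d.]+)\s+Eh", "hartree"),
    "anisotropic_xc": (r"::\s+-> anisotropic XC\s+(-?[\d.]+)\s+Eh", "hartree"),
    "isotropic_xc": (r"::\s+-> isotropic XC\s+(-?[\d.]+)\s+Eh", "hartree"),
    "dispersion_energy": (r"::\s+-> dispersion\s+(-?[\d.]+)\s+Eh", "hartree"),
    "repulsion_energy": (r"::\s+repulsion energy\s+(-?[\d.]+)\s+Eh", "hartree"),
    "atomization_energy": (r"::\s+atomisation energy\s+(-?[\d.]+)\s+Eh", "hartree"),
}

_UNIT_FACTORS = {
    "hartree": HARTREE_TO_KCAL,
    "ev": 1.0,
    "hartree_per_bohr": HARTREE_TO_KCAL / BOHR_TO_ANGSTROM,
}


def parse_xtb_output(
    text: str,
    vacuum: bool,
    patterns: Mapping[str, tuple[str, str]] = XTB_OUTPUT_PATTERNS,
) -> EnergyAttributes:
    """Extract the 18 attributes from an engine stdout log.

    For vacuum runs the engine omits the solvation block; the five solvation
    fields are filled with exact zeros.  Attribute 2 (total free energy
    without cavitation and hydrogen-bond contributions) is computed as the
    printed total free energy minus the printed Gsasa and Ghb terms — mapping
    "cavitation" onto the surface (Gsasa) term is a documented choice.
    """

    def grab(key: str, required: bool = True) -> float | None:
        regex, unit = patterns[key]
        m = re.search(regex, text)
        if m is None:
            if required:
                raise EngineParseError(f"attribute {key!r} not found in engine output")
            return None
        return float(m.group(1)) * _UNIT_FACTORS[unit]

    solv_required = not vacuum
    values: dict[str, float] = {}
    for field in (
        "total_energy", "homo_lumo_gap", "homo_eigenvalue", "lumo_eigenvalue",
        "scc_energy", "gradient_norm", "isotropic_es", "anisotropic_xc",
        "isotropic_xc", "dispersion_energy", "repulsion_energy",
        "atomization_energy",
    ):
        values[field] = grab(field)  # type: ignore[assignment]
    for field in _SOLVATION_FIELDS:
        v = grab(field, required=solv_required)
        values[field] = 0.0 if vacuum else float(v)  # type: ignore[arg-type]
    free_energy = grab("free_energy", required=solv_required)
    if free_energy is None:
        free_energy = values["total_energy"]
    values["total_free_energy_no_cav_hb"] = free_energy - values["g_cav"] - values["g_hb"]
    return EnergyAttributes(**values)


class XtbEngine:
    """Adapter driving an external GFN2-xTB binary with ALPB solvation.

    Invokes ``<binary> <xyz> --gfn 2 --chrg <q> [--alpb <solvent>]`` in a
    scratch directory per (molecule, medium) call and parses stdout via the
    pattern table.  No caching by default.
    """

    name = "xtb"

    def __init__(
        self,
        binary: str = "xtb",
        patterns: Mapping[str, tuple[str, str]] = XTB_OUTPUT_PATTERNS,
    ) -> None:
        self.binary = binary
        self.patterns = patterns

    def compute(self, molecule: Molecule, medium: Medium) -> EnergyAttributes:
        with tempfile.TemporaryDirectory(prefix="imperham_xtb_") as scratch:
            xyz = Path(scratch) / "input.xyz"
            write_structures([molecule], xyz)
            cmd = [self.binary, str(xyz), "--gfn", "2", "--chrg", str(molecule.net_charge)]
            if molecule.spin_multiplicity != 1:
                cmd += ["--uhf", str(molecule.spin_multiplicity - 1)]
            if not medium.is_vacuum:
                cmd += ["--alpb", medium.engine_key or medium.name]
            try:
                proc = subprocess.run(
                    cmd, capture_output=True, text=True, cwd=scratch, check=False
                )
            except FileNotFoundError as exc:
                raise EngineUnavailableError(
                    f"engine binary {self.binary!r} not found"
                ) from exc
            if proc.returncode != 0:
                raise EngineUnavailableError(
                    f"engine exited with status {proc.returncode}",
                    log=proc.stdout + proc.stderr,
                )
            return parse_xtb_output(proc.stdout, vacuum=medium.is_vacuum,
                                    patterns=self.patterns)


class MediaPanelError(RuntimeError):
    """One or more media failed; per-medium errors are in ``failures``."""

    def __init__(self, failures: dict[str, Exception]) -> None:
        super().__init__(
            "media failed: " + ", ".join(f"{k} ({v})" for k, v in failures.items())
        )
        self.failures = failures


def run_media_panel(
    engine,
    molecule: Molecule,
    media: Sequence[Medium],
    allow_partial: bool = False,
) -> dict[str, EnergyAttributes]:
    """Compute attributes for one molecule across a media panel.

    Failures are collected per medium; by default any failure raises a
    :class:`MediaPanelError` listing every failing medium, or pass
    ``allow_partial=True`` to get the successful subset.
    """
    names = [m.name for m in media]
    if len(set(names)) != len(names):
        raise ValueError("media names must be unique within a panel")
    results: dict[str, EnergyAttributes] = {}
    failures: dict[str, Exception] = {}
    for medium in media:
        try:
            results[medium.name] = engine.compute(molecule, medium)
        except Exception as exc:  # reported per-medium, never silently dropped
            failures[medium.name] = exc
    if failures and not allow_partial:
        raise MediaPanelError(failures)
    return results
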