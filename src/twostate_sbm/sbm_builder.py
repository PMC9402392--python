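"""Dual-basin Cα structure-based model (SBM) assembly and evaluation.

The potential is built from a reference (open-state) structure and a
classified contact map:

.. code-block:: text

    E =   Σ_bonds     K_r (r - r0)²
        + Σ_angles    K_θ (θ - θ0)²
        + Σ_dihedrals Σ_{n=1,3} K_φ(n) (1 - cos n(φ - φ0))
        + Σ_common    ε_DG ([1 + (σ^NC/r)¹²][1 + G(r, r₁)][1 + G(r, r₂)] - 1)
        + Σ_specific  ε (5 (σ/r)¹² - 6 (σ/r)¹⁰)
        + Σ_noncontact ε₄ (σ^NC/r)¹²

with G(r, rₙ) = -exp(-(r - rₙ)²/(2 σ_g²)).  Bonded native values come
from the open-state geometry.  Common contacts get a dual-Gaussian well
with one minimum at the open-state Cα distance (r₁) and one at the
closed-state distance (r₂), each of depth exactly ε_DG; state-specific
contacts get single-minimum 10–12 wells at their own state's distance.
Open-specific contacts involving the C-terminal tail helix are scaled by
``cth_scale`` (the knob that strengthens or removes the tail's grip on
the open state).

Default force constants: K_r = 100, K_θ = 20, K_φ(1) = 1, K_φ(3) = 0.5,
ε₄ = ε = 1, σ^NC = 0.4 nm, Gaussian width 0.05 nm — all in reduced units
where ε = 1 kJ/mol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels
from .contact_map import ContactMap
from .structure_io import Structure

__all__ = [
    "ModelParams",
    "BondedTerms",
    "DualGaussianContact",
    "SpecificContact",
    "SBMTopology",
    "build_topology",
    "dual_gaussian_energy",
    "lj1012_energy",
    "excluded_volume_energy",
    "total_energy",
    "forces",
    "export_topology",
    "import_topology",
    "export_gromacs",
]

K_R = 100.0
K_THETA = 20.0
K_PHI_1 = 1.0
K_PHI_3 = 0.5
EV_CUTOFF = 2.5  # nm; unshifted EV term < 1e-9 eps here for sigma_nc = 0.4

COMPONENT_NAMES = ("bond", "angle", "dihedral", "dual_gaussian",
                   "specific_open", "specific_closed", "excluded")


@dataclass
class ModelParams:
    """Tunable strengths of the dual-basin model (reduced units)."""

    eps_unit: float = 1.0
    eps_os: float = 1.0  # open-state specific contact strength (× ε)
    eps_cs: float = 1.0  # closed-state specific contact strength (× ε)
    eps_dg: float = 1.0  # dual-Gaussian well depth
    eps_ev: float = 1.0  # excluded-volume prefactor ε₄
    sigma_nc: float = 0.4  # excluded-volume core, nm
    gauss_width: float = 0.05  # Gaussian well width σ_g, nm
    cth_scale: float = 1.0  # multiplier on ε_OS for tail-helix contacts
    cth_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("eps_os", "eps_cs", "eps_dg", "eps_ev", "cth_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_nc <= 0 or self.gauss_width <= 0:
            raise ValueError("sigma_nc and gauss_width must be positive")


@dataclass
class BondedTerms:
    bond_idx: np.ndarray  # (nb, 2) bead indices
    bond_r0: np.ndarray
    angle_idx: np.ndarray  # (na, 3)
    angle_theta0: np.ndarray
    dihedral_idx: np.ndarray  # (nd, 4)
    dihedral_phi0: np.ndarray


@dataclass
class DualGaussianContact:
    i: int
    j: int
    r1: float  # open-state native Cα distance, nm
    r2: float  # closed-state native Cα distance, nm
    depth: float = 1.0
    width: float = 0.05
    core: float = 0.4


@dataclass
class SpecificContact:
    i: int
    j: int
    sigma: float  # native Cα distance in its own state, nm
    strength: float
    is_closed: bool = False


@dataclass
class SBMTopology:
    n_beads: int
    auth_ids: list[int]  # bead index -> author residue id
    bonded: BondedTerms
    dual_gaussian: list[DualGaussianContact]
    specific: list[SpecificContact]
    ev_idx: np.ndarray  # (nev, 2) excluded-volume pair list
    params: ModelParams

    _arrays: dict = field(default_factory=dict, repr=False)

    def bead_index(self, auth_id: int) -> int:
        try:
            return self.auth_ids.index(auth_id)
        except ValueError:
            raise KeyError(f"residue {auth_id} not in topology") from None

    def kernel_arrays(self) -> dict:
        """Flat numpy arrays for the numba kernels (cached)."""
        if not self._arrays:
            ndg = len(self.dual_gaussian)
            nsp = len(self.specific)
            self._arrays = dict(
                bond_idx=self.bonded.bond_idx,
                bond_r0=self.bonded.bond_r0,
                k_r=K_R,
                angle_idx=self.bonded.angle_idx,
                angle_theta0=self.bonded.angle_theta0,
                k_theta=K_THETA,
                dihedral_idx=self.bonded.dihedral_idx,
                dihedral_phi0=self.bonded.dihedral_phi0,
                k_phi1=K_PHI_1,
                k_phi3=K_PHI_3,
                dg_idx=np.array([[c.i, c.j] for c in self.dual_gaussian],
                                dtype=np.int64).reshape(ndg, 2),
                dg_r1=np.array([c.r1 for c in self.dual_gaussian]),
                dg_r2=np.array([c.r2 for c in self.dual_gaussian]),
                eps_dg=self.params.eps_dg,
                sigma_nc=self.params.sigma_nc,
                gauss_width=self.params.gauss_width,
                spec_idx=np.array([[c.i, c.j] for c in self.specific],
                                  dtype=np.int64).reshape(nsp, 2),
                spec_sigma=np.array([c.sigma for c in self.specific]),
                spec_strength=np.array([c.strength for c in self.specific]),
                spec_is_closed=np.array([c.is_closed for c in self.specific],
                                        dtype=np.bool_),
                ev_idx=self.ev_idx,
                eps_ev=self.params.eps_ev,
                ev_cutoff=EV_CUTOFF,
            )
        return self._arrays


def _signed_dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def build_topology(open_ref: Structure, cm: ContactMap, params: ModelParams) -> SBMTopology:
    """Assemble the dual-basin topology from the open-state reference.

    Bonded native values are measured on the open-state Cα trace; the
    classified contact map supplies the non-bonded terms.  ``discarded``
    records contribute nothing (their pairs fall back to excluded volume).
    """
    coords = open_ref.ca_coords()
    auth_ids = open_ref.auth_ids
    n = len(auth_ids)
    index = {a: k for k, a in enumerate(auth_ids)}

    bond_idx = np.array([[k, k + 1] for k in range(n - 1)], dtype=np.int64)
    bond_r0 = np.array([np.linalg.norm(coords[k + 1] - coords[k])
                        for k in range(n - 1)])
    angle_idx = np.array([[k, k + 1, k + 2] for k in range(n - 2)],
                         dtype=np.int64).reshape(max(n - 2, 0), 3)
    angle_theta0 = np.array([_angle(coords[k], coords[k + 1], coords[k + 2])
                             for k in range(n - 2)])
    dihedral_idx = np.array([[k, k + 1, k + 2, k + 3] for k in range(n - 3)],
                            dtype=np.int64).reshape(max(n - 3, 0), 4)
    dihedral_phi0 = np.array(
        [_signed_dihedral(coords[k], coords[k + 1], coords[k + 2], coords[k + 3])
         for k in range(n - 3)]
    )
    bonded = BondedTerms(bond_idx, bond_r0, angle_idx, angle_theta0,
                         dihedral_idx, dihedral_phi0)

    dg: list[DualGaussianContact] = []
    spec: list[SpecificContact] = []
    contact_pairs: set[tuple[int, int]] = set()
    for rec in cm.records:
        if rec.klass == "discarded":
            continue
        if rec.res_i not in index or rec.res_j not in index:
            raise KeyError(
                f"contact residue pair ({rec.res_i},{rec.res_j}) missing "
                "from the reference structure"
            )
        i, j = index[rec.res_i], index[rec.res_j]
        contact_pairs.add((min(i, j), max(i, j)))
        if rec.klass == "common":
            dg.append(DualGaussianContact(i, j, rec.d_open, rec.d_closed,
                                          params.eps_dg, params.gauss_width,
                                          params.sigma_nc))
        elif rec.klass == "open_specific":
            strength = params.eps_os * (params.cth_scale if rec.involves_cth else 1.0)
            spec.append(SpecificContact(i, j, rec.d_open, strength, is_closed=False))
        elif rec.klass == "closed_specific":
            spec.append(SpecificContact(i, j, rec.d_closed, params.eps_cs,
                                        is_closed=True))

    ev = [(i, j) for i in range(n) for j in range(i + 4, n)
          if (i, j) not in contact_pairs]
    ev_idx = np.array(ev, dtype=np.int64).reshape(len(ev), 2)
    return SBMTopology(n, list(auth_ids), bonded, dg, spec, ev_idx, params)


# -- closed-form single-term energies (reference path, used in tests/docs) --

def dual_gaussian_energy(r: float, c: DualGaussianContact) -> float:
    """ε_DG ([1 + (σ^NC/r)¹²][1 + G(r,r₁)][1 + G(r,r₂)] − 1); −ε_DG at r₁ and r₂."""
    if r <= 0:
        raise ValueError("r must be positive")
    g1 = -np.exp(-((r - c.r1) ** 2) / (2 * c.width ** 2))
    g2 = -np.exp(-((r - c.r2) ** 2) / (2 * c.width ** 2))
    return float(c.depth * ((1 + (c.core / r) ** 12) * (1 + g1) * (1 + g2) - 1))


def lj1012_energy(r: float, c: SpecificContact) -> float:
    """10–12 well: strength·(5(σ/r)¹² − 6(σ/r)¹⁰); minimum −strength at r = σ."""
    if r <= 0:
        raise ValueError("r must be positive")
    sr = c.sigma / r
    return float(c.strength * (5 * sr ** 12 - 6 * sr ** 10))


def excluded_volume_energy(r: float, params: ModelParams) -> float:
    """Purely repulsive ε₄ (σ^NC/r)¹² (untruncated closed form)."""
    if r <= 0:
        raise ValueError("r must be positive")
    return float(params.eps_ev * (params.sigma_nc / r) ** 12)


def _evaluate(top: SBMTopology, coords: np.ndarray):
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (top.n_beads, 3):
        raise ValueError(f"coords shape {coords.shape} != ({top.n_beads}, 3)")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinate")
    return _kernels.energy_forces(coords, **top.kernel_arrays())


def total_energy(top: SBMTopology, coords: np.ndarray) -> dict[str, float]:
    """Energy decomposition; ``total`` is the exact sum of the components."""
    comps, _ = _evaluate(top, coords)
    out = {name: float(v) for name, v in zip(COMPONENT_NAMES, comps)}
    out["total"] = float(comps.sum())
    return out


def forces(top: SBMTopology, coords: np.ndarray) -> np.ndarray:
    """Analytic forces F = −∇E, shape (n_beads, 3), in ε/nm."""
    _, f = _evaluate(top, coords)
    return f


# -- serialization --

def export_topology(top: SBMTopology, path: str | Path, format: str = "native_json") -> None:
    if format == "native_json":
        doc = {
            "n_beads": top.n_beads,
            "auth_ids": top.auth_ids,
            "params": {**asdict(top.params),
                       "cth_range": list(top.params.cth_range)
                       if top.params.cth_range else None},
            "bonds": [[int(i), int(j), float(r0)] for (i, j), r0 in
                      zip(top.bonded.bond_idx, top.bonded.bond_r0)],
            "angles": [[int(i), int(j), int(k), float(t0)] for (i, j, k), t0 in
                       zip(top.bonded.angle_idx, top.bonded.angle_theta0)],
            "dihedrals": [[int(i), int(j), int(k), int(l), float(p0)]
                          for (i, j, k, l), p0 in
                          zip(top.bonded.dihedral_idx, top.bonded.dihedral_phi0)],
            "dual_gaussian": [asdict(c) for c in top.dual_gaussian],
            "specific": [asdict(c) for c in top.specific],
            "ev_pairs": top.ev_idx.tolist(),
        }
        Path(path).write_text(json.dumps(doc))
    elif format == "gromacs_dialect":
        export_gromacs(top, Path(path))
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_topology(path: str | Path) -> SBMTopology:
    doc = json.loads(Path(path).read_text())
    p = dict(doc["params"])
    if p.get("cth_range"):
        p["cth_range"] = tuple(p["cth_range"])
    params = ModelParams(**p)
    bonds = doc["bonds"]
    angles = doc["angles"]
    dihedrals = doc["dihedrals"]
    bonded = BondedTerms(
        np.array([b[:2] for b in bonds], dtype=np.int64).reshape(len(bonds), 2),
        np.array([b[2] for b in bonds]),
        np.array([a[:3] for a in angles], dtype=np.int64).reshape(len(angles), 3),
        np.array([a[3] for a in angles]),
        np.array([d[:4] for d in dihedrals], dtype=np.int64).reshape(len(dihedrals), 4),
        np.array([d[4] for d in dihedrals]),
    )
    dg = [DualGaussianContact(**c) for c in doc["dual_gaussian"]]
    spec = [SpecificContact(**c) for c in doc["specific"]]
    ev = np.array(doc["ev_pairs"], dtype=np.int64).reshape(len(doc["ev_pairs"]), 2)
    return SBMTopology(doc["n_beads"], list(doc["auth_ids"]), bonded, dg, spec,
                       ev, params)


def export_gromacs(top: SBMTopology, stem: Path,
                   coords: np.ndarray | None = None) -> tuple[Path, Path]:
    """Write ``<stem>.top`` / ``<stem>.gro`` in a documented SBM pairs dialect.

    Bonds/angles/dihedrals use standard function types; common contacts are
    written as ``[ pairs ]`` lines ``i j 6 r1 r2 width depth`` (a Gaussian
    dialect an external engine would map onto tabulated potentials), and
    specific contacts as 10–12 pairs ``i j 1 C12 C10``.
    """
    stem = Path(stem)
    top_path = stem.with_suffix(".top")
    gro_path = stem.with_suffix(".gro")
    lines = ["; dual-basin Calpha SBM topology", "[ atoms ]"]
    for k in range(top.n_beads):
        lines.append(f"{k + 1:6d}  CA  {top.auth_ids[k]:6d}")
    lines.append("[ bonds ]")
    for (i, j), r0 in zip(top.bonded.bond_idx, top.bonded.bond_r0):
        lines.append(f"{i + 1:6d} {j + 1:6d} 1 {r0:.6f} {2 * K_R:.3f}")
    lines.append("[ angles ]")
    for (i, j, k), t0 in zip(top.bonded.angle_idx, top.bonded.angle_theta0):
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d} 1 "
                     f"{np.degrees(t0):.4f} {2 * K_THETA:.3f}")
    lines.append("[ dihedrals ]")
    for (i, j, k, l), p0 in zip(top.bonded.dihedral_idx, top.bonded.dihedral_phi0):
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d} {l + 1:6d} 1 "
                     f"{np.degrees(p0):.4f} {K_PHI_1:.3f} 1")
        lines.append(f"{i + 1:6d} {j + 1:6d} {k + 1:6d} {l + 1:6d} 1 "
                     f"{np.degrees(p0):.4f} {K_PHI_3:.3f} 3")
    lines.append("[ pairs ]")
    for c in top.dual_gaussian:
        lines.append(f"{c.i + 1:6d} {c.j + 1:6d} 6 {c.r1:.6f} {c.r2:.6f} "
                     f"{c.width:.4f} {c.depth:.4f}")
    for c in top.specific:
        c12 = 5 * c.strength * c.sigma ** 12
        c10 = 6 * c.strength * c.sigma ** 10
        lines.append(f"{c.i + 1:6d} {c.j + 1:6d} 1 {c12:.6e} {c10:.6e}")
    lines.append("[ exclusions ]")
    lines.append(f"; {len(top.ev_idx)} excluded-volume pairs, "
                 f"sigma_nc={top.params.sigma_nc}")
    top_path.write_text("\n".join(lines) + "\n")

    if coords is None:
        coords = np.zeros((top.n_beads, 3))
    gro = ["dual-basin Calpha SBM coordinates", f"{top.n_beads:5d}"]
    for k in range(top.n_beads):
        x, y, z = coords[k]
        gro.append(f"{k + 1:5d}GLY   CA {k + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    gro.append(f"{20.0:10.5f}{20.0:10.5f}{20.0:10.5f}")
    gro_path.write_text("\n".join(gro) + "\n")
    return top_path, gro_path
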