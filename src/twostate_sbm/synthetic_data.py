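"""Download-free synthetic fixtures for the full pipeline.

``make_two_state_toy`` builds a Cα-only model protein with the same
architecture as a two-lobed periplasmic binding protein: a fixed lobe
(lobe 1), a mobile lobe (lobe 2) that swings about a hinge axis between
an *open* and a *closed* pose, and an optional C-terminal tail segment
(the tail-helix analog) that touches lobe 2 only in the open state.
The two conformers are exactly rigid within each segment, so contact
classification on them has unambiguous ground truth:

* pairs inside one rigid unit keep their distance → ``common``;
* lobe 1 × lobe 2 pairs touch only in the closed pose → ``closed_specific``;
* tail × lobe 2 pairs touch only in the open pose → ``open_specific``.

The hinge segments leave the rotation axis tangentially (circular arcs),
so beads next to the hinge pivots barely move and the closed conformer
costs little bonded strain in a model whose bonded terms come from the
open reference — which is what lets the toy actually interconvert in
Langevin dynamics at the default reduced temperature.

``make_rc_series`` and ``make_salt_bridge_fixture`` provide planted
reaction-coordinate series and all-atom salt-bridge poses for the
analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_map import ContactMap, build_contact_map
from .structure_io import Atom, ResidueRecord, Structure

__all__ = [
    "ToySpec",
    "ToyResult",
    "make_two_state_toy",
    "make_rc_series",
    "make_salt_bridge_fixture",
]

# helix discretization: consecutive beads 0.38 nm apart, alpha-like
_HELIX_RADIUS = 0.23
_HELIX_TURN = 1.75  # rad per bead


@dataclass
class ToySpec:
    """Construction parameters of the synthetic two-state protein."""

    n_lobe1: int = 14
    n_lobe2: int = 14
    n_tail: int = 6
    hinge_angle: float = 100.0  # degrees between open and closed pose
    bond_length: float = 0.38  # nm, Cα virtual bond
    lobe2_offset: float = 0.9  # nm, lobe-2 helix axis height above hinge axis
    lobe1_offset: float = 1.75  # nm, lobe-1 helix axis height (closed side)
    contact_cutoff: float = 0.8  # nm, Cα detection cutoff used for planting
    min_contacts_per_class: int = 1
    jitter: float = 0.004  # nm, seeded positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lobe1, self.n_lobe2) < 5 or (0 < self.n_tail < 2):
            raise ValueError("lobe bead counts must be >= 5 (tail >= 2 or 0)")
        if not (20.0 < self.hinge_angle < 120.0):
            raise ValueError("hinge_angle must lie in (20, 120) degrees")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


@dataclass
class ToyResult:
    open: Structure
    closed: Structure
    contacts: ContactMap  # planted ground-truth classification
    segments: dict[str, tuple[int, int]]  # auth-id ranges per segment
    cth_range: tuple[int, int] | None
    rc_pair: tuple[int, int]  # suggested reaction-coordinate residue pair
    rmsd: float  # all-bead open/closed RMSD, nm


def _helix(n: int, x0: float, direction: float, center_yz: np.ndarray,
           phase: float, bond: float) -> np.ndarray:
    """Beads on a helix with axis along x; consecutive spacing = ``bond``."""
    chord = 2.0 * _HELIX_RADIUS * np.sin(_HELIX_TURN / 2.0)
    rise = np.sqrt(max(bond ** 2 - chord ** 2, 1e-6))
    out = np.empty((n, 3))
    for k in range(n):
        ang = phase + _HELIX_TURN * k
        out[k, 0] = x0 + direction * rise * k
        out[k, 1] = center_yz[0] + _HELIX_RADIUS * np.cos(ang)
        out[k, 2] = center_yz[1] + _HELIX_RADIUS * np.sin(ang)
    return out


# lateral zigzag applied to arc/line beads: keeps native bend angles near
# 150 deg, away from the collinear singularity of the angle potential
_ZIGZAG = 0.055


def _arc_from_axis(start_x: float, u_dir: np.ndarray, offset: float,
                   bond: float, x_sign: float = 1.0) -> np.ndarray:
    """Circular arc leaving the x-axis tangentially at ``start_x``.

    Rises to perpendicular ``offset`` along unit yz-direction ``u_dir``;
    returns the intermediate beads (excluding the on-axis start point).
    Tangential departure keeps beads near the pivot almost on the axis,
    which is what makes the hinge cheap to rotate.  Beads zigzag
    out-of-plane by ±``_ZIGZAG``.
    """
    alpha = np.radians(55.0)
    radius = offset / (1.0 - np.cos(alpha))
    arc_len = radius * alpha
    n = max(int(round(arc_len / bond)), 2)
    w = np.array([0.0, -u_dir[1], u_dir[0]])  # out-of-plane unit vector
    pts = []
    for k in range(1, n + 1):
        a = alpha * k / n
        x = start_x + x_sign * radius * np.sin(a)
        perp = radius * (1.0 - np.cos(a))
        zig = _ZIGZAG if k % 2 else -_ZIGZAG
        pts.append(np.array([x, perp * u_dir[0], perp * u_dir[1]]) + zig * w)
    return np.array(pts)


def _line(a: np.ndarray, b: np.ndarray, bond: float,
          include_start: bool = False, include_end: bool = False) -> np.ndarray:
    """Beads along segment a→b, zigzagging laterally around the straight line."""
    length = float(np.linalg.norm(b - a))
    n_gap = max(int(round(length / bond)), 1)
    t_hat = (b - a) / length
    ref = np.array([0.0, 0.0, 1.0]) if abs(t_hat[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(t_hat, ref)
    w /= np.linalg.norm(w)
    pts = []
    for k in range(0 if include_start else 1,
                   n_gap + 1 if include_end else n_gap):
        zig = 0.0 if k in (0, n_gap) else (_ZIGZAG if k % 2 else -_ZIGZAG)
        pts.append(a + (k / n_gap) * (b - a) + zig * w)
    return np.array(pts)


def _rotate_about_x(coords: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    out = coords.copy()
    out[:, 1] = coords[:, 1] * c - coords[:, 2] * s
    out[:, 2] = coords[:, 1] * s + coords[:, 2] * c
    return out


def _as_structure(coords: np.ndarray, title: str) -> Structure:
    residues = [
        ResidueRecord(k + 1, "GLY", [Atom("CA", "C", coords[k])])
        for k in range(len(coords))
    ]
    return Structure("A", residues, title)


def _build_geometry(spec: ToySpec, rng: np.random.Generator):
    """Returns (open_coords, closed_coords, segment index ranges)."""
    bond = spec.bond_length
    phi = np.radians(spec.hinge_angle)
    u_open = np.array([1.0, 0.0])  # yz direction of lobe 2 in the open pose
    u_closed = np.array([np.cos(phi), np.sin(phi)])  # where lobe 2 lands

    # mobile lobe: arc up from pivot P, helix, arc back down to pivot Q
    up_arc = _arc_from_axis(0.0, u_open, spec.lobe2_offset - _HELIX_RADIUS,
                            bond)
    h2_start_x = up_arc[-1, 0] + 0.38
    helix2 = _helix(spec.n_lobe2, h2_start_x, +1.0,
                    np.array([spec.lobe2_offset, 0.0]), np.pi, bond)
    end = helix2[-1]
    rho = float(np.hypot(end[1], end[2]))
    u_end = np.array([end[1], end[2]]) / rho
    # mirror arc: place Q so the reversed arc's far end coincides with the
    # helix terminus, then walk it back down to the axis
    down_arc_rev = _arc_from_axis(0.0, u_end, rho, bond, x_sign=-1.0)
    q_x = end[0] - down_arc_rev[-1, 0]
    down_arc = (down_arc_rev + np.array([q_x, 0.0, 0.0]))[::-1][1:]

    # fixed lobe 1 faces the closed pose of lobe 2
    helix1 = _helix(spec.n_lobe1, h2_start_x + (spec.n_lobe2 - 1) * 0.14,
                    -1.0, spec.lobe1_offset * u_closed, 0.0, bond)
    p_point = np.zeros(3)
    hinge_a = _line(helix1[-1], p_point, bond, include_end=True)

    q_point = np.array([q_x, 0.0, 0.0])

    parts = [("lobe1", helix1), ("hinge_a", hinge_a), ("lobe2_up", up_arc),
             ("lobe2", helix2), ("lobe2_down", down_arc), ("hinge_q", q_point[None, :])]

    if spec.n_tail:
        tail_anchor = np.array([end[0] + 0.1, 1.42, 0.52])
        tail_ramp = _line(q_point, tail_anchor, bond, include_end=False)
        tail = np.array([
            tail_anchor + np.array([-bond * k, 0.0,
                                    _ZIGZAG if k % 2 else -_ZIGZAG])
            for k in range(spec.n_tail)
        ])
        parts += [("tail_ramp", tail_ramp), ("tail", tail)]

    names, ranges, blocks = [], {}, []
    k = 0
    for name, block in parts:
        names.append(name)
        ranges[name] = (k, k + len(block))  # 0-based, half-open
        blocks.append(block)
        k += len(block)
    base = np.vstack(blocks)
    base += rng.normal(0.0, spec.jitter, size=base.shape)

    mobile = np.zeros(len(base), dtype=bool)
    for name in ("lobe2_up", "lobe2", "lobe2_down"):
        lo, hi = ranges[name]
        mobile[lo:hi] = True

    open_coords = base
    closed_coords = base.copy()
    closed_coords[mobile] = _rotate_about_x(base[mobile], phi)
    return open_coords, closed_coords, ranges, mobile


def make_two_state_toy(spec: ToySpec | None = None) -> ToyResult:
    """Build the synthetic open/closed conformer pair with planted contacts.

    The returned contact map is produced by Cα-cutoff detection at the
    construction cutoff and ratio 1.5, and its classes are validated
    against the segment ground truth (rigid-unit membership).  If the
    jittered geometry produces a steric clash (< 0.35 nm non-bonded) or
    misses a contact class, construction retries with a derived seed and
    eventually raises.
    """
    spec = spec or ToySpec()
    last_error = None
    for attempt in range(5):
        rng = np.random.Generator(
            np.random.PCG64([spec.seed, attempt]))
        try:
            return _try_build(spec, rng)
        except RuntimeError as exc:  # clash or missing class: jitter again
            last_error = exc
    raise RuntimeError(
        f"toy construction failed after 5 attempts: {last_error}")


def _try_build(spec: ToySpec, rng: np.random.Generator) -> ToyResult:
    open_coords, closed_coords, ranges, mobile = _build_geometry(spec, rng)
    n = len(open_coords)

    # non-bonded = separation >= 4, matching the model's exclusion rule
    for label, coords in (("open", open_coords), ("closed", closed_coords)):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        ii, jj = np.triu_indices(n, k=4)
        dmin = dist[ii, jj].min()
        if dmin < 0.35:
            raise RuntimeError(f"steric clash in {label} state: {dmin:.3f} nm")

    rmsd = float(np.sqrt(np.mean(np.sum((open_coords - closed_coords) ** 2,
                                        axis=1))))
    if spec.hinge_angle > 0 and rmsd < 0.3:
        raise RuntimeError(f"open/closed RMSD {rmsd:.3f} nm < 0.3 nm")

    # native bend angles must stay away from the collinear singularity
    for coords in (open_coords, closed_coords):
        u = coords[:-2] - coords[1:-1]
        v = coords[2:] - coords[1:-1]
        cosang = np.sum(u * v, -1) / (np.linalg.norm(u, axis=1)
                                      * np.linalg.norm(v, axis=1))
        worst = np.degrees(np.arccos(np.clip(cosang, -1, 1))).max()
        if worst > 163.0:
            raise RuntimeError(f"near-collinear bend angle {worst:.1f} deg")

    open_s = _as_structure(open_coords, "synthetic two-state toy (open)")
    closed_s = _as_structure(closed_coords, "synthetic two-state toy (closed)")

    cth_range = None
    if spec.n_tail:
        lo = ranges["tail_ramp"][0]
        cth_range = (lo + 1, n)  # auth ids

    cm = build_contact_map(open_s, closed_s, mode="ca_cutoff",
                           cutoff=spec.contact_cutoff, min_seq_sep=4,
                           ratio=1.5, cth_range=cth_range)
    cm.parameters["generator"] = "make_two_state_toy"
    cm.parameters["seed"] = spec.seed

    # ground-truth audit against rigid-unit membership
    counts = {"common": 0, "open_specific": 0, "closed_specific": 0}
    for rec in cm.records:
        i0, j0 = rec.res_i - 1, rec.res_j - 1
        cross = mobile[i0] != mobile[j0]
        if rec.klass == "common":
            counts["common"] += 1
            if not cross and abs(rec.d_open - rec.d_closed) > 3 * spec.jitter:
                raise RuntimeError(
                    f"rigid-unit pair ({rec.res_i},{rec.res_j}) changed "
                    "distance between states")
        elif rec.klass in ("open_specific", "closed_specific"):
            counts[rec.klass] += 1
            if not cross:
                raise RuntimeError(
                    f"intra-unit pair ({rec.res_i},{rec.res_j}) labelled "
                    f"{rec.klass}")
    for klass, c in counts.items():
        if c < spec.min_contacts_per_class:
            raise RuntimeError(f"only {c} {klass} contacts planted")

    # reaction coordinate: lobe-1 core bead vs lobe-2 core bead
    rc_i = (ranges["lobe1"][0] + ranges["lobe1"][1]) // 2 + 1
    rc_j = (ranges["lobe2"][0] + ranges["lobe2"][1]) // 2 + 1
    segments = {name: (lo + 1, hi) for name, (lo, hi) in ranges.items()}
    return ToyResult(open_s, closed_s, cm, segments, cth_range,
                     (rc_i, rc_j), rmsd)


def make_rc_series(
    basin_means: tuple[float, float],
    widths: tuple[float, float] = (0.08, 0.08),
    switch_prob: float = 0.001,
    n: int = 10000,
    seed: int = 0,
    weights: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state hidden path with Gaussian emissions.

    Returns ``(series, path)`` where ``path[k]`` ∈ {0, 1} indexes the
    basin of frame k.  With ``weights`` given, states are drawn i.i.d.
    with those probabilities instead of following a symmetric switching
    chain (useful for planted-occupancy tests); ``switch_prob = 0``
    keeps the initial state forever.
    """
    m = np.asarray(basin_means, dtype=float)
    w = np.asarray(widths, dtype=float)
    if m[0] == m[1]:
        raise ValueError("basin means must be distinct")
    if (w <= 0).any():
        raise ValueError("widths must be positive")
    if not (0.0 <= switch_prob < 1.0):
        raise ValueError("switch_prob must be in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    if weights is not None:
        p1 = weights[1] / (weights[0] + weights[1])
        path = (rng.random(n) < p1).astype(np.int8)
    else:
        flips = rng.random(n) < switch_prob
        path = np.zeros(n, dtype=np.int8)
        state = 0
        for k in range(n):
            if flips[k]:
                state = 1 - state
            path[k] = state
    series = rng.normal(m[path], w[path])
    series = np.clip(series, 1e-3, None)  # distances stay positive
    return series, path


# -- all-atom salt-bridge fixture ------------------------------------------

def _asp_residue(auth_id: int) -> ResidueRecord:
    """ASP with its carboxylate oxygens; OD1 at the origin."""
    atoms = [
        Atom("OD1", "O", np.array([0.0, 0.0, 0.0])),
        Atom("OD2", "O", np.array([-0.15, 0.16, 0.0])),
        Atom("CG", "C", np.array([-0.08, 0.08, 0.0])),
        Atom("CB", "C", np.array([-0.16, 0.21, 0.1])),
        Atom("CA", "C", np.array([-0.25, 0.33, 0.05])),
        Atom("N", "N", np.array([-0.38, 0.30, 0.0])),
        Atom("C", "C", np.array([-0.24, 0.47, 0.12])),
        Atom("O", "O", np.array([-0.14, 0.52, 0.19])),
    ]
    return ResidueRecord(auth_id, "ASP", atoms)


def _lys_residue(auth_id: int, nz: np.ndarray) -> ResidueRecord:
    """LYS whose ammonium nitrogen NZ sits at ``nz``; chain trails in +x."""
    d = np.array([1.0, 0.0, 0.0])
    atoms = [
        Atom("NZ", "N", nz),
        Atom("CE", "C", nz + 0.15 * d),
        Atom("CD", "C", nz + 0.30 * d + np.array([0.0, 0.1, 0.0])),
        Atom("CG", "C", nz + 0.45 * d),
        Atom("CB", "C", nz + 0.60 * d + np.array([0.0, 0.1, 0.0])),
        Atom("CA", "C", nz + 0.75 * d),
        Atom("N", "N", nz + 0.85 * d + np.array([0.0, 0.1, 0.0])),
        Atom("C", "C", nz + 0.85 * d + np.array([0.0, -0.1, 0.05])),
        Atom("O", "O", nz + 0.95 * d + np.array([0.0, -0.15, 0.1])),
    ]
    return ResidueRecord(auth_id, "LYS", atoms)


def make_salt_bridge_fixture(
    distance_schedule: list[float],
    acidic_id: int = 10,
    basic_id: int = 20,
) -> list[Structure]:
    """All-atom frames with a planted ASP–LYS closest O–N distance.

    Frame ``t`` poses LYS so that the NZ–OD1 distance equals
    ``distance_schedule[t]`` (within 1e-3 nm) and every other O–N pair
    is strictly longer.
    """
    frames = []
    for t, d in enumerate(distance_schedule):
        if d <= 0.2:
            raise ValueError(
                f"schedule entry {t}: distance {d} nm <= 0.2 nm is infeasible")
        nz = np.array([d, -0.05, 0.0])
        nz *= d / np.linalg.norm(nz)  # exact |NZ - OD1| = d, tilted off OD2
        res = [_asp_residue(acidic_id), _lys_residue(basic_id, nz)]
        frames.append(Structure("A", sorted(res, key=lambda r: r.auth_seq_id),
                                title=f"salt-bridge fixture frame {t}"))
    return frames
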