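"""Native contact detection and two-state classification.

Contacts are detected independently in the open- and closed-state
structures and then classified:

* detected in both states → ``common`` (later modelled as a dual-Gaussian
  well with one minimum per state);
* detected only in one state → ``open_specific`` / ``closed_specific``
  provided the distance in the *other* state is more than ``ratio``
  (default 1.5×, strict) times the distance in the state where the
  contact exists;
* detected in exactly one state but failing the ratio test → ``discarded``
  (reported, but excluded from the potential).

Detection defaults to an all-heavy-atom proximity criterion (any
inter-residue heavy-atom pair within 0.45 nm) with a minimum sequence
separation of 4; a pure Cα-cutoff mode is available for Cα-only models.
The distances stored on each record are always Cα–Cα distances in the
two native structures, since the model is Cα-resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Structure, StructureError

__all__ = [
    "ContactRecord",
    "ContactMap",
    "CLASSES",
    "detect_contacts",
    "classify",
    "build_contact_map",
    "class_counts",
    "write_contact_map",
    "read_contact_map",
]

CLASSES = ("common", "open_specific", "closed_specific", "discarded")


@dataclass
class ContactRecord:
    res_i: int
    res_j: int
    d_open: float  # Cα–Cα, nm, in the open structure
    d_closed: float  # Cα–Cα, nm, in the closed structure
    present_open: bool
    present_closed: bool
    klass: str
    involves_cth: bool = False

    def __post_init__(self) -> None:
        if self.res_i >= self.res_j:
            raise ValueError(f"require res_i < res_j, got ({self.res_i},{self.res_j})")
        if self.klass not in CLASSES:
            raise ValueError(f"unknown contact class {self.klass!r}")


@dataclass
class ContactMap:
    records: list[ContactRecord]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(r.res_i, r.res_j) for r in self.records]
        if len(set(pairs)) != len(pairs):
            dup = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValueError(f"duplicate contact pairs: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self, klass: str) -> list[ContactRecord]:
        return [r for r in self.records if r.klass == klass]


def detect_contacts(
    s: Structure,
    mode: str = "all_atom",
    cutoff: float = 0.45,
    min_seq_sep: int = 4,
) -> dict[tuple[int, int], float]:
    """Detect residue–residue contacts in one structure.

    Returns ``{(i, j): ca_distance_nm}`` with ``i < j`` author ids and
    ``j - i >= min_seq_sep``.  In ``all_atom`` mode a pair is in contact
    when *any* heavy-atom pair across the two residues is within
    ``cutoff``; in ``ca_cutoff`` mode when the Cα–Cα distance is within
    ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("all_atom", "ca_cutoff"):
        raise ValueError(f"unknown detection mode {mode!r}")

    ids = np.array(s.auth_ids)
    if mode == "ca_cutoff":
        coords = s.ca_coords()
        owner = np.arange(len(ids))
    else:
        coords_list, owner_list = [], []
        for k, r in enumerate(s.residues):
            for a in r.atoms:
                if a.element != "H":
                    coords_list.append(a.position)
                    owner_list.append(k)
        coords = np.asarray(coords_list)
        owner = np.asarray(owner_list)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts: set[tuple[int, int]] = set()
    for a, b in pairs:
        ri, rj = owner[a], owner[b]
        if ri == rj:
            continue
        i, j = (ids[ri], ids[rj]) if ids[ri] < ids[rj] else (ids[rj], ids[ri])
        if j - i >= min_seq_sep:
            contacts.add((int(i), int(j)))

    out: dict[tuple[int, int], float] = {}
    for i, j in sorted(contacts):
        ri, rj = s.residue(i), s.residue(j)
        if not (ri.has_ca and rj.has_ca):
            raise StructureError(f"contact pair ({i},{j}) lacks a CA atom")
        out[(i, j)] = float(np.linalg.norm(ri.ca - rj.ca))
    return out


def classify(
    open_pairs: set[tuple[int, int]],
    closed_pairs: set[tuple[int, int]],
    d_open: dict[tuple[int, int], float],
    d_closed: dict[tuple[int, int], float],
    ratio: float = 1.5,
    cth_range: tuple[int, int] | None = None,
    parameters: dict | None = None,
) -> ContactMap:
    """Classify detected contacts into the four classes.

    ``d_open``/``d_closed`` must provide the Cα–Cα distance of every pair
    in *both* structures regardless of where it was detected.  The ratio
    test is strict (``>``), so a pair sitting exactly at ``ratio`` times
    its in-state distance is discarded.
    """
    records = []
    for i, j in sorted(open_pairs | closed_pairs):
        pair = (i, j)
        for d, tag in ((d_open, "open"), (d_closed, "closed")):
            if pair not in d:
                raise KeyError(f"missing {tag}-state distance for pair {pair}")
        po, pc = pair in open_pairs, pair in closed_pairs
        do, dc = d_open[pair], d_closed[pair]
        if po and pc:
            klass = "common"
        elif pc and do > ratio * dc:
            klass = "closed_specific"
        elif po and dc > ratio * do:
            klass = "open_specific"
        else:
            klass = "discarded"
        cth = cth_range is not None and (
            cth_range[0] <= i <= cth_range[1] or cth_range[0] <= j <= cth_range[1]
        )
        records.append(ContactRecord(i, j, do, dc, po, pc, klass, cth))
    params = dict(parameters or {})
    params["ratio"] = ratio
    if cth_range is not None:
        params["cth_range"] = list(cth_range)
    return ContactMap(records, params)


def build_contact_map(
    open_state: Structure,
    closed_state: Structure,
    mode: str = "all_atom",
    cutoff: float = 0.45,
    min_seq_sep: int = 4,
    ratio: float = 1.5,
    cth_range: tuple[int, int] | None = None,
) -> ContactMap:
    """Detect contacts in both conformers (shared residues only) and classify."""
    shared = set(open_state.auth_ids) & set(closed_state.auth_ids)

    def restrict(d: dict) -> dict:
        return {p: v for p, v in d.items() if p[0] in shared and p[1] in shared}

    det_open = restrict(detect_contacts(open_state, mode, cutoff, min_seq_sep))
    det_closed = restrict(detect_contacts(closed_state, mode, cutoff, min_seq_sep))
    union = set(det_open) | set(det_closed)
    d_open = {p: _ca_dist(open_state, p) for p in union}
    d_closed = {p: _ca_dist(closed_state, p) for p in union}
    params = {"mode": mode, "cutoff": cutoff, "min_seq_sep": min_seq_sep}
    return classify(set(det_open), set(det_closed), d_open, d_closed,
                    ratio=ratio, cth_range=cth_range, parameters=params)


def _ca_dist(s: Structure, pair: tuple[int, int]) -> float:
    return float(np.linalg.norm(s.residue(pair[0]).ca - s.residue(pair[1]).ca))


def class_counts(cm: ContactMap) -> dict[str, int]:
    """Count records per class, plus open-specific contacts involving the tail helix."""
    counts = {k: 0 for k in CLASSES}
    counts["open_specific_cth"] = 0
    for r in cm.records:
        counts[r.klass] += 1
        if r.klass == "open_specific" and r.involves_cth:
            counts["open_specific_cth"] += 1
    return counts


_COLUMNS = ["i", "j", "d_open", "d_closed", "present_open", "present_closed",
            "class", "involves_cth"]


def write_contact_map(cm: ContactMap, path: str | Path) -> None:
    """Serialize as TSV; detection parameters go into ``# key=value`` header lines."""
    rows = [
        (r.res_i, r.res_j, f"{r.d_open:.6f}", f"{r.d_closed:.6f}",
         int(r.present_open), int(r.present_closed), r.klass, int(r.involves_cth))
        for r in cm.records
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w") as fh:
        for key, value in cm.parameters.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_contact_map(path: str | Path) -> ContactMap:
    params: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for n, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = n
            break
        key, _, value = line[1:].strip().partition("=")
        params[key.strip()] = _parse_param(value)
    import io as _io

    try:
        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
        df = df[_COLUMNS]
    except Exception as exc:
        raise ValueError(f"malformed contact map {path}: {exc}") from exc
    records = []
    for n, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ContactRecord(int(row.i), int(row.j), float(row.d_open),
                              float(row.d_closed), bool(row.present_open),
                              bool(row.present_closed), str(row._6),
                              bool(row.involves_cth))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed contact map row at line {body_start + n + 2}: {exc}"
            ) from exc
    return ContactMap(records, params)


def _parse_param(value: str):
    value = value.strip()
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.startswith("["):
        import ast

        return ast.literal_eval(value)
    return value
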