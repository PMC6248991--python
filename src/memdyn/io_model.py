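"""Topology/trajectory data model, readers and writers, and the atom-selection grammar.

Every downstream analysis stage consumes ``(Trajectory, Selection)`` pairs built
here; no stage re-parses files.  Conventions at the boundary:

* coordinates are in Å, times in ps, boxes orthorhombic ``(Lx, Ly, Lz)`` in Å;
* residue numbering is author-provided (1-based biological numbering, e.g. the
  D358–C646 transmembrane range of a class-A GPCR model);
* atom indexing is internal and 0-based.

Supported containers: a strict PDB ATOM/HETATM subset, DCD and XTC (through
MDAnalysis), and a hand-writable plain frame-table text format (see
``docs/frame_table_format.md``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SEGMENT_LABELS",
    "Topology",
    "Trajectory",
    "Selection",
    "TopologyError",
    "TrajectoryError",
    "SelectionError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "select",
]


class TopologyError(ValueError):
    """Malformed topology file or segment configuration."""


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory data."""


class SelectionError(ValueError):
    """Unparseable selection expression or unknown label."""


#: Segment vocabulary: seven transmembrane helices, the amphipathic helix 8,
#: intra/extracellular loops, termini, and non-protein groups.
SEGMENT_LABELS = (
    ["TM%d" % i for i in range(1, 8)]
    + ["H8"]
    + ["IL%d" % i for i in range(1, 4)]
    + ["EL%d" % i for i in range(1, 4)]
    + ["NT", "CT", "LIPID", "WATER", "ION", "OTHER"]
)

_WATER_RESNAMES = {"HOH", "TIP3", "TIP", "WAT", "SOL", "SPC", "W"}
_ION_RESNAMES = {"NA", "CL", "K", "SOD", "CLA", "POT", "MG", "CA2", "ZN"}
_LIPID_RESNAMES = {"SDPC", "POPC", "DPPC", "DOPC", "POPE", "LIP", "PC", "PE"}


@dataclass
class Topology:
    """Per-atom labels anchoring all selections.

    Parallel arrays indexed by the internal 0-based atom index.
    """

    names: np.ndarray  # str, atom names (PDB convention, e.g. "CA", "OW")
    elements: np.ndarray  # str, element symbols
    resids: np.ndarray  # int, author (biological) residue numbers
    resnames: np.ndarray  # str, 3-letter residue names
    chains: np.ndarray  # str, chain identifiers
    segments: np.ndarray  # str, one of SEGMENT_LABELS
    masses: np.ndarray | None = None  # amu, optional

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        self.segments = np.asarray(self.segments, dtype=object)
        n = len(self.names)
        for arr, what in [
            (self.elements, "elements"),
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.chains, "chains"),
            (self.segments, "segments"),
        ]:
            if len(arr) != n:
                raise TopologyError(f"{what} has length {len(arr)}, expected {n}")
        bad = sorted(set(self.segments) - set(SEGMENT_LABELS))
        if bad:
            raise TopologyError(f"unknown segment labels: {bad}")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != n:
                raise TopologyError("masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_segment(self, resid: int) -> str:
        """Segment label of a protein residue number (first matching atom)."""
        idx = np.nonzero(self.resids == resid)[0]
        if idx.size == 0:
            raise TopologyError(f"no atoms with residue number {resid}")
        return str(self.segments[idx[0]])


@dataclass
class Trajectory:
    """frames × atoms × 3 coordinates (Å) with per-frame times (ps) and boxes (Å)."""

    coordinates: np.ndarray  # (F, N, 3) float
    times: np.ndarray  # (F,) ps, strictly increasing
    box: np.ndarray | None = None  # (F, 3) orthorhombic (Lx, Ly, Lz), Å
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                f"coordinates must be (frames, atoms, 3); got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise TrajectoryError("trajectory must contain at least one frame")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise TrajectoryError("box must be per-frame (Lx, Ly, Lz)")
        if self.topology is not None and self.topology.n_atoms != self.n_atoms:
            raise TrajectoryError(
                f"topology has {self.topology.n_atoms} atoms, "
                f"coordinates have {self.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords, whitespace-separated):
#   expr    := term (("or") term)*
#   term    := factor (("and") factor)*
#   factor  := "not" factor | "(" expr ")" | primitive
#   primitive :=
#       "name"    NAME[,NAME...]          atom names, "*" wildcard suffix ok
#       "element" SYM[,SYM...]
#       "resid"   A[-B][,C[-D]...]        author residue numbers, inclusive
#       "segment" LABEL[,LABEL...]        "TM*"-style wildcards ok
#       "chain"   ID[,ID...]
#       "resname" NAME[,NAME...]
#       "protein" | "water" | "lipid" | "all"

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class Selection:
    """A predicate over topology atoms, e.g. ``"name CA and resid 358-646"``.

    Evaluating the same selection twice on the same topology yields identical,
    atom-index-ordered results (the predicate never looks at coordinates).
    """

    expression: str

    def indices(self, topology: Topology) -> np.ndarray:
        return select(topology, self)


def _match_list(values: np.ndarray, patterns: Iterable[str]) -> np.ndarray:
    mask = np.zeros(len(values), dtype=bool)
    vals = np.array([str(v).upper() for v in values], dtype=object)
    for pat in patterns:
        pat = pat.upper()
        if "*" in pat:
            rx = re.compile("^" + re.escape(pat).replace(r"\*", ".*") + "$")
            mask |= np.array([bool(rx.match(v)) for v in vals])
        else:
            mask |= vals == pat
    return mask


class _SelectionParser:
    def __init__(self, expression: str, topology: Topology):
        self.tokens = _TOKEN_RE.findall(expression)
        if not self.tokens:
            raise SelectionError("empty selection expression")
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens near {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("dangling operator in selection")
        if tok.lower() == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        key = self.next().lower()
        top = self.top
        if key == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if key == "protein":
            return ~_match_list(top.segments, ["LIPID", "WATER", "ION"])
        if key == "water":
            return _match_list(top.segments, ["WATER"])
        if key == "lipid":
            return _match_list(top.segments, ["LIPID"])
        if key in ("name", "element", "segment", "chain", "resname"):
            args = self.next().split(",")
            if key == "segment":
                known = set(SEGMENT_LABELS)
                for a in args:
                    if "*" not in a and a.upper() not in known:
                        raise SelectionError(f"unknown segment label {a!r}")
            col = {
                "name": top.names,
                "element": top.elements,
                "segment": top.segments,
                "chain": top.chains,
                "resname": top.resnames,
            }[key]
            return _match_list(col, args)
        if key == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for part in self.next().split(","):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", part)
                if not m:
                    raise SelectionError(f"bad residue range {part!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask |= (top.resids >= lo) & (top.resids <= hi)
            return mask
        raise SelectionError(f"unknown selection keyword {key!r}")


def select(topology: Topology, selection: Selection | str) -> np.ndarray:
    """Evaluate a selection, returning sorted 0-based atom indices.

    An expression matching nothing returns an empty array (not an error);
    referencing an unknown segment label is an error.
    """
    expr = selection.expression if isinstance(selection, Selection) else selection
    mask = _SelectionParser(expr, topology).parse()
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# Segment configuration
# ---------------------------------------------------------------------------

def load_segment_config(source: str | Path | dict) -> dict[str, list[tuple[int, int]]]:
    """Load segment → residue-range mapping from YAML (or an equivalent dict).

    Format::

        segments:
          TM1: [[358, 390]]
          TM2: [[395, 425]]

    Ranges are inclusive author residue numbers.  Overlapping ranges across
    segments are a configuration error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    if not isinstance(data, dict):
        raise TopologyError("segment config must be a mapping")
    raw = data.get("segments", data)
    out: dict[str, list[tuple[int, int]]] = {}
    covered: dict[int, str] = {}
    for label, ranges in raw.items():
        if label not in SEGMENT_LABELS:
            raise TopologyError(f"unknown segment label {label!r} in config")
        spans = []
        for rng in ranges:
            lo, hi = int(rng[0]), int(rng[1])
            if hi < lo:
                raise TopologyError(f"inverted range {rng} for segment {label}")
            for r in range(lo, hi + 1):
                if r in covered and covered[r] != label:
                    raise TopologyError(
                        f"residue {r} assigned to both {covered[r]} and {label}"
                    )
                covered[r] = label
            spans.append((lo, hi))
        out[label] = spans
    return out


def segment_of_residue(
    resid: int, config: dict[str, list[tuple[int, int]]]
) -> str | None:
    for label, spans in config.items():
        for lo, hi in spans:
            if lo <= resid <= hi:
                return label
    return None


# ---------------------------------------------------------------------------
# PDB reading / writing (strict ATOM/HETATM subset)
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    # two-letter elements in common MD systems
    for two in ("CL", "NA", "MG", "ZN", "FE", "BR"):
        if stripped.upper() == two:
            return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def read_topology(
    path: str | Path,
    segment_config: str | Path | dict | None = None,
) -> Topology:
    """Parse a PDB file's ATOM/HETATM records into a :class:`Topology`.

    Protein residues are mapped to segments through ``segment_config``;
    unmapped protein residues get OTHER.  Waters, lipids and ions are
    classified by residue name.  A duplicate atom serial number or a malformed
    record is a hard error (with its line number), never a silent fix.
    """
    config = load_segment_config(segment_config) if segment_config is not None else {}
    names, elements, resids, resnames, chains, segments, masses = (
        [], [], [], [], [], [], [],
    )
    seen_serials: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TopologyError(
                    f"{path}: line {lineno}: truncated {rec} record"
                )
            serial = line[6:11].strip()
            if serial in seen_serials:
                raise TopologyError(
                    f"{path}: line {lineno}: duplicate atom serial {serial}"
                )
            seen_serials.add(serial)
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or "A"
            try:
                resid = int(line[22:26])
            except ValueError as exc:
                raise TopologyError(
                    f"{path}: line {lineno}: bad residue number {line[22:26]!r}"
                ) from exc
            for col in (line[30:38], line[38:46], line[46:54]):
                try:
                    float(col)
                except ValueError as exc:
                    raise TopologyError(
                        f"{path}: line {lineno}: bad coordinate field {col!r}"
                    ) from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            element = element.capitalize() if element else _guess_element(name)
            upper = resname.upper()
            if upper in _WATER_RESNAMES:
                seg = "WATER"
            elif upper in _ION_RESNAMES:
                seg = "ION"
            elif upper in _LIPID_RESNAMES:
                seg = "LIPID"
            else:
                seg = segment_of_residue(resid, config) or "OTHER"
            names.append(name)
            elements.append(element)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            segments.append(seg)
            masses.append(_MASSES.get(element.upper()[:1] if len(element) == 1 else element.upper(), 0.0))
    if not names:
        raise TopologyError(f"{path}: no ATOM/HETATM records found")
    return Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=chains, segments=segments, masses=np.array(masses),
    )


def write_topology(
    path: str | Path, topology: Topology, coordinates: np.ndarray
) -> None:
    """Write one conformation as a minimal PDB file (ATOM records + END)."""
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.shape != (topology.n_atoms, 3):
        raise TopologyError("coordinates shape must be (n_atoms, 3)")
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            name = str(topology.names[i])
            # PDB name column alignment: 1-letter elements start in column 14
            pname = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                "ATOM  {serial:>5d} {name:4s} {res:<3s} {chain:1s}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=i + 1,
                    name=pname,
                    res=str(topology.resnames[i]),
                    chain=str(topology.chains[i])[:1],
                    resid=int(topology.resids[i]),
                    x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                    occ=1.0, b=0.0,
                    el=str(topology.elements[i])[:2],
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------

def _read_frame_table(path: str | Path, topology: Topology | None) -> Trajectory:
    """Read the repo's plain frame-table text format.

    Layout (whitespace-separated)::

        # natoms N
        # frame <time_ps> <Lx> <Ly> <Lz>
        x y z              (N rows)
        # frame ...

    The box triplet is optional but must be consistent across frames.
    """
    coords: list[np.ndarray] = []
    times: list[float] = []
    boxes: list[tuple[float, float, float]] = []
    have_box: bool | None = None
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[:2] != ["#", "natoms"]:
            raise TrajectoryError(f"{path}: first line must be '# natoms N'")
        n_atoms = int(header[2])
        if topology is not None and topology.n_atoms != n_atoms:
            raise TrajectoryError(
                f"{path}: file has {n_atoms} atoms, topology has {topology.n_atoms}"
            )
        frame_idx = -1
        while True:
            line = fh.readline()
            if not line:
                break
            parts = line.split()
            if not parts:
                continue
            if parts[0] != "#" or parts[1] != "frame":
                raise TrajectoryError(f"{path}: expected '# frame' header, got {line!r}")
            frame_idx += 1
            times.append(float(parts[2]))
            if len(parts) >= 6:
                if have_box is False:
                    raise TrajectoryError(f"{path}: inconsistent box metadata")
                have_box = True
                boxes.append((float(parts[3]), float(parts[4]), float(parts[5])))
            else:
                if have_box is True:
                    raise TrajectoryError(f"{path}: inconsistent box metadata")
                have_box = False
            frame = np.empty((n_atoms, 3))
            for a in range(n_atoms):
                row = fh.readline()
                if not row:
                    raise TrajectoryError(
                        f"{path}: truncated final frame {frame_idx} "
                        f"(got {a} of {n_atoms} atom rows)"
                    )
                vals = row.split()
                if len(vals) != 3:
                    raise TrajectoryError(
                        f"{path}: frame {frame_idx}: bad coordinate row {row!r}"
                    )
                frame[a] = [float(v) for v in vals]
            coords.append(frame)
    if not coords:
        raise TrajectoryError(f"{path}: no frames")
    return Trajectory(
        coordinates=np.array(coords),
        times=np.array(times),
        box=np.array(boxes) if have_box else None,
        topology=topology,
    )


def _write_frame_table(path: str | Path, trajectory: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write(f"# natoms {trajectory.n_atoms}\n")
        for f in range(trajectory.n_frames):
            if trajectory.box is not None:
                bx = trajectory.box[f]
                fh.write(
                    "# frame %.8g %.8g %.8g %.8g\n"
                    % (trajectory.times[f], bx[0], bx[1], bx[2])
                )
            else:
                fh.write("# frame %.8g\n" % trajectory.times[f])
            np.savetxt(fh, trajectory.coordinates[f], fmt="%.8f")


def _read_mda(path: str | Path, topology: Topology, dt: float | None) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(str(path))
    except (OSError, ValueError, EOFError) as exc:
        raise TrajectoryError(f"{path}: {exc}") from exc
    if u.atoms.n_atoms != topology.n_atoms:
        raise TrajectoryError(
            f"{path}: file has {u.atoms.n_atoms} atoms, "
            f"topology has {topology.n_atoms}"
        )
    coords, times, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) if dt is None else i * dt)
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                dims = ts.dimensions
                if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                    raise TrajectoryError(
                        f"{path}: non-orthorhombic box not supported "
                        f"(angles {dims[3:6]})"
                    )
                boxes.append(dims[:3].astype(float).copy())
    times_arr = np.asarray(times, dtype=float)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        # containers without time metadata: fall back to unit spacing
        times_arr = np.arange(len(times_arr), dtype=float)
    return Trajectory(
        coordinates=np.array(coords),
        times=times_arr,
        box=np.array(boxes) if len(boxes) == len(coords) else None,
        topology=topology,
    )


def _write_mda(path: str | Path, trajectory: Trajectory) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(trajectory.n_atoms, trajectory=True)
    dt = (
        float(trajectory.times[1] - trajectory.times[0])
        if trajectory.n_frames > 1
        else 1.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=trajectory.n_atoms, dt=dt) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[f]
                u.trajectory.ts.frame = f
                u.trajectory.ts.time = float(trajectory.times[f])
                u.trajectory.ts.dt = dt
                if trajectory.box is not None:
                    u.dimensions = np.concatenate(
                        [trajectory.box[f], [90.0, 90.0, 90.0]]
                    )
                w.write(u.atoms)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    dt: float | None = None,
) -> Trajectory:
    """Read a trajectory (DCD, XTC, or plain frame table) against a topology.

    ``dt`` (ps) overrides per-frame times with a uniform stride, e.g. the 4-ps
    sampling used for covariance analysis; otherwise times come from file
    metadata.  Atom-count mismatch against the topology is an error.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".dcd", ".xtc"):
        traj = _read_mda(path, topology, dt)
    else:
        traj = _read_frame_table(path, topology)
        if dt is not None:
            traj = Trajectory(
                coordinates=traj.coordinates,
                times=np.arange(traj.n_frames) * dt,
                box=traj.box,
                topology=topology,
            )
    return traj


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory in the container implied by the file suffix."""
    suffix = Path(path).suffix.lower()
    if suffix in (".dcd", ".xtc"):
        _write_mda(path, trajectory)
    else:
        _write_frame_table(path, trajectory)
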