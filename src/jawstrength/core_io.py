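"""Data model, file readers/writers and study configuration.

The pipeline compares in vivo bite forces of island lizard populations with
in silico jaw-strength estimates computed from population-average mandible
shapes.  Everything downstream consumes the types defined here:

* :class:`SpecimenRecord` — one animal's linear measurements, collection
  metadata and (for field-caught animals) its bite force.
* :class:`LandmarkSet` — a 3D landmark configuration in one of two regimes:
  16 fixed landmarks over the whole mandible, or 7 fixed landmarks plus four
  semilandmark curves on the dentary.
* :class:`SurfaceMesh` — a triangle surface mesh (mm) used as the warping
  reference and the finite-element input.
* :class:`StudyConfig` — every tunable the pipeline exposes, with the study
  defaults (999 permutations, 10 sliding iterations, 13–16 semilandmarks per
  curve, the four muscle force proportions, bone elastic constants).

All coordinates are 3D, in millimetres, right-handed.  Missing values are
encoded as empty fields, never zero.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("jawstrength")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class JawstrengthError(Exception):
    """Base class for all package errors."""


class FormatError(JawstrengthError):
    """A file could not be parsed or is missing required structure."""


class ValidationError(JawstrengthError):
    """Parsed data violate a domain invariant."""


class DegenerateInputError(JawstrengthError):
    """Input is technically well formed but analytically degenerate."""


# ---------------------------------------------------------------------------
# Specimen records
# ---------------------------------------------------------------------------

MEASUREMENTS = ("svl", "hh", "pl", "pw", "mw")
#: the eight study populations (islets of the Pityusic archipelago)
DEFAULT_POPULATIONS = (
    "Bleda Plana",
    "Conillera",
    "Es Pouas",
    "Es Vedra",
    "Espardell",
    "Espartar",
    "Penjats",
    "Trocadors",
)

SEXES = ("male", "female", "unknown")
METHODS = ("fieldwork", "alcohol")


@dataclass(frozen=True)
class SpecimenRecord:
    """One lizard: linear measurements (mm) plus collection metadata.

    ``bite_force`` (N) is present only for field-measured animals;
    ``collection_year`` only for alcohol-preserved museum specimens.
    """

    specimen_id: str
    population: str
    sex: str
    method: str
    svl: float
    hh: float
    pl: float
    pw: float
    mw: float
    bite_force: float | None = None
    collection_year: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: method must be one of "
                f"{METHODS}, got {self.method!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )
        for name in MEASUREMENTS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: {name.upper()} must be a "
                    f"positive finite length in mm, got {v!r}"
                )
        if self.method == "fieldwork":
            if self.collection_year is not None:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: collection_year is only "
                    "valid for alcohol-preserved specimens"
                )
        else:
            if self.bite_force is not None:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: bite_force is only valid "
                    "for fieldwork specimens"
                )
        if self.bite_force is not None and (
            not np.isfinite(self.bite_force) or self.bite_force <= 0
        ):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: bite_force must be positive, "
                f"got {self.bite_force!r}"
            )

    @property
    def measurements(self) -> np.ndarray:
        """The five linear measurements as a vector (SVL, HH, PL, PW, MW)."""
        return np.array([getattr(self, m) for m in MEASUREMENTS], dtype=float)


_SPECIMEN_COLUMNS = ("specimen_id", "population", "sex", "method") + MEASUREMENTS


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen measurement table (CSV).

    Required columns: specimen_id, population, sex, method, svl, hh, pl,
    pw, mw (case-insensitive).  Optional: bite_force, collection_year.
    Empty cells are missing values, never zero.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"specimen table not found: {path}")
    df = pd.read_csv(path, dtype={"specimen_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _SPECIMEN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"specimen table {path} is missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        bite = row.get("bite_force")
        year = row.get("collection_year")
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                population=str(row["population"]),
                sex=str(row["sex"]).lower(),
                method=str(row["method"]).lower(),
                svl=float(row["svl"]),
                hh=float(row["hh"]),
                pl=float(row["pl"]),
                pw=float(row["pw"]),
                mw=float(row["mw"]),
                bite_force=None if pd.isna(bite) else float(bite),
                collection_year=None if pd.isna(year) else int(year),
            )
        )
    return records


def write_specimen_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "population": r.population,
                "sex": r.sex,
                "method": r.method,
                **{m: getattr(r, m) for m in MEASUREMENTS},
                "bite_force": r.bite_force,
                "collection_year": r.collection_year,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def records_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Tabular view of a record list (one row per specimen)."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "population": [r.population for r in records],
            "sex": [r.sex for r in records],
            "method": [r.method for r in records],
            **{m: [getattr(r, m) for r in records] for m in MEASUREMENTS},
            "bite_force": [r.bite_force for r in records],
            "collection_year": [r.collection_year for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Landmark sets (NTS-dialect text files)
# ---------------------------------------------------------------------------

REGIMES = ("mandible16", "dentary_curves")
N_FIXED = {"mandible16": 16, "dentary_curves": 7}
N_CURVES = {"mandible16": 0, "dentary_curves": 4}


@dataclass(frozen=True)
class LandmarkSet:
    """Fixed landmarks plus (optionally) semilandmark curves, mm, 3D.

    ``fixed`` is a (k, 3) array; ``curves`` a tuple of (m_i, 3) arrays whose
    first and last points are anatomical anchors (they never slide).
    """

    specimen_id: str
    regime: str
    fixed: np.ndarray
    curves: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown landmark regime {self.regime!r}")
        fixed = np.asarray(self.fixed, dtype=float)
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(
            self, "curves", tuple(np.asarray(c, dtype=float) for c in self.curves)
        )
        if fixed.ndim != 2 or fixed.shape[1] != 3:
            raise ValidationError("fixed landmarks must be a (k, 3) matrix")
        if fixed.shape[0] != N_FIXED[self.regime]:
            raise ValidationError(
                f"regime {self.regime!r} requires {N_FIXED[self.regime]} fixed "
                f"landmarks, got {fixed.shape[0]}"
            )
        if len(self.curves) != N_CURVES[self.regime]:
            raise ValidationError(
                f"regime {self.regime!r} requires {N_CURVES[self.regime]} "
                f"curves, got {len(self.curves)}"
            )
        for i, c in enumerate(self.curves):
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
                raise ValidationError(
                    f"curve {i + 1} must be a (m>=3, 3) matrix, got {c.shape}"
                )
        all_pts = self.all_points()
        if not np.all(np.isfinite(all_pts)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite landmark coordinate"
            )

    def all_points(self) -> np.ndarray:
        """Fixed landmarks followed by all curve points, row-stacked."""
        parts = [self.fixed, *self.curves]
        return np.vstack(parts) if self.curves else self.fixed.copy()


def _nts_tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_landmarks(path: str | Path, regime: str) -> LandmarkSet:
    """Read an NTS-dialect landmark matrix.

    The dialect accepts whitespace- or comma-separated numbers and ignores
    comment lines starting with a quote character (' or ").  The header row
    is either the classic ``1 <k>[L] <dim> 0 [dim=3]`` form or a bare
    ``<k> <dim>`` pair.  For the dentary regime a comment line of the form
    ``" curves m1 m2 m3 m4`` must state the curve point counts; the matrix
    then holds the 7 fixed landmarks followed by the concatenated curves.
    """
    path = Path(path)
    if regime not in REGIMES:
        raise ValidationError(f"unknown landmark regime {regime!r}")
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    curve_counts: list[int] | None = None
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line[0] in "'\"":
            body = line.lstrip("'\"").strip()
            if body.lower().startswith("curves"):
                try:
                    curve_counts = [int(t) for t in _nts_tokens(body)[1:]]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad curve-count comment: {body!r}"
                    ) from exc
            continue
        if header is None:
            header = _nts_tokens(line)
            continue
        try:
            rows.append([float(t) for t in _nts_tokens(line)])
        except ValueError:
            bad = next(t for t in _nts_tokens(line) if not _is_number(t))
            raise FormatError(
                f"{path}:{lineno}: non-numeric token {bad!r} in coordinate row"
            ) from None
    if header is None:
        raise FormatError(f"{path}: empty landmark file")
    k, dim = _parse_nts_header(header, path)
    if dim != 3:
        raise FormatError(f"{path}: expected 3D coordinates, header says {dim}")
    flat = [v for row in rows for v in row]
    if len(flat) != k * 3:
        raise ValidationError(
            f"{path}: header promises {k} points x 3 coordinates, found "
            f"{len(flat)} values"
        )
    coords = np.array(flat, dtype=float).reshape(k, 3)

    n_fixed = N_FIXED[regime]
    if regime == "mandible16":
        if k != n_fixed:
            raise ValidationError(
                f"{path}: regime mandible16 requires 16 points, file has {k}"
            )
        return LandmarkSet(path.stem, regime, coords)
    if curve_counts is None:
        raise FormatError(
            f"{path}: dentary_curves files need a '\" curves m1 m2 m3 m4' "
            "comment giving per-curve point counts"
        )
    if len(curve_counts) != N_CURVES[regime]:
        raise ValidationError(
            f"{path}: expected {N_CURVES[regime]} curve counts, got "
            f"{len(curve_counts)}"
        )
    if n_fixed + sum(curve_counts) != k:
        raise ValidationError(
            f"{path}: {n_fixed} fixed + curves {curve_counts} != {k} points"
        )
    curves = []
    start = n_fixed
    for m in curve_counts:
        curves.append(coords[start : start + m])
        start += m
    return LandmarkSet(path.stem, regime, coords[:n_fixed], tuple(curves))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _parse_nts_header(tokens: list[str], path: Path) -> tuple[int, int]:
    ints = []
    for t in tokens:
        t = t.rstrip("Ll")
        if t.lower().startswith("dim="):
            t = t[4:]
        try:
            ints.append(int(t))
        except ValueError:
            continue
    if len(ints) >= 3 and ints[0] == 1:
        return ints[1], ints[2]
    if len(ints) >= 2:
        return ints[0], ints[1]
    raise FormatError(f"{path}: cannot parse NTS header {tokens!r}")


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    """Write an NTS-dialect file that :func:`read_landmarks` round-trips."""
    path = Path(path)
    pts = lms.all_points()
    lines = [f'" specimen {lms.specimen_id} regime {lms.regime}']
    if lms.curves:
        counts = " ".join(str(c.shape[0]) for c in lms.curves)
        lines.append(f'" curves {counts}')
    lines.append(f"1 {pts.shape[0]}L 3 0 dim=3")
    for p in pts:
        lines.append(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Surface meshes (PLY / STL via trimesh)
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be triangles (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError("face references an invalid vertex index")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def validate(self, min_area: float = 1e-14) -> None:
        if np.any(self.face_areas() <= min_area):
            raise ValidationError("mesh contains zero-area faces")


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a PLY or STL triangle mesh; polygonal (quad) faces are rejected."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    if path.suffix.lower() == ".ply":
        _reject_nontriangle_ply(path)
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # trimesh raises various types on bad input
        raise FormatError(f"cannot parse mesh {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path}: no triangle faces found")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _reject_nontriangle_ply(path: Path) -> None:
    """Scan an ascii PLY for non-triangle faces (binary PLY is left to trimesh)."""
    with open(path, "rb") as fh:
        head = fh.read(512)
    if b"format ascii" not in head:
        return
    text = path.read_text(errors="replace").splitlines()
    try:
        end = next(i for i, l in enumerate(text) if l.strip() == "end_header")
        counts = {}
        order = []
        for l in text[:end]:
            t = l.split()
            if len(t) == 3 and t[0] == "element":
                counts[t[1]] = int(t[2])
                order.append(t[1])
    except (StopIteration, ValueError) as exc:
        raise FormatError(f"{path}: malformed PLY header") from exc
    offset = end + 1
    for name in order:
        if name == "face":
            for l in text[offset : offset + counts[name]]:
                t = l.split()
                if t and int(t[0]) != 3:
                    raise FormatError(
                        f"{path}: only triangle faces are supported "
                        f"(found a {t[0]}-gon)"
                    )
        offset += counts[name]


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a mesh as ascii PLY or binary STL, by extension."""
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
    elif suffix == ".stl":
        data = trimesh.exchange.stl.export_stl(tm)
    else:
        raise FormatError(f"unsupported mesh format {suffix!r} (use .ply or .stl)")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def merge_vertices(mesh: SurfaceMesh, tol: float = 1e-9) -> SurfaceMesh:
    """Merge coincident vertices within ``tol`` mm (e.g. after STL export)."""
    tm = mesh.to_trimesh()
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=int(-np.log10(tol)))
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

#: muscle-group force proportions at a 35 deg gape (fraction of bite force):
#: combined external adductor + adductor posterior, pseudotemporalis, and the
#: pterygoideus resultant split half external / half internal.
DEFAULT_MUSCLE_WEIGHTS = {
    "adductor_combined": 0.481,
    "pseudotemporalis": 0.316,
    "pterygoideus_external": 0.102,
    "pterygoideus_internal": 0.102,
}

#: cortical bone, isotropic linear elastic.  Units: N and mm, so the Young's
#: modulus is in N/mm^2 (MPa); 17 GPa = 17000 MPa.
DEFAULT_YOUNG_MODULUS_MPA = 17_000.0
DEFAULT_POISSON_RATIO = 0.3


@dataclass
class StudyConfig:
    """All pipeline tunables, with study defaults."""

    input_dir: Path | None = None
    out_dir: Path | None = None
    seed: int = 1
    n_permutations: int = 999
    n_slide_iterations: int = 10
    semilandmark_range: tuple[int, int] = (13, 16)
    muscle_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_MUSCLE_WEIGHTS)
    )
    young_modulus: float = DEFAULT_YOUNG_MODULUS_MPA
    poisson_ratio: float = DEFAULT_POISSON_RATIO
    sex_filter: str = "total"
    fe_edge_fraction: float = 0.04  # characteristic FE edge as fraction of jaw length
    stress_quantile: float = 0.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.n_slide_iterations < 1:
            raise ValidationError("n_slide_iterations must be >= 1")
        lo, hi = self.semilandmark_range
        if not (3 <= lo <= hi):
            raise ValidationError("semilandmark_range must satisfy 3 <= lo <= hi")
        total = sum(self.muscle_weights.values())
        if abs(total - 1.0) > 0.01:
            raise ValidationError(
                f"muscle weights must sum to 1 within 0.01, got {total:.4f}"
            )
        if self.sex_filter not in ("total", "male"):
            raise ValidationError("sex_filter must be 'total' or 'male'")
        if not (0 < self.poisson_ratio < 0.5) or self.young_modulus <= 0:
            raise ValidationError("elastic constants out of range")
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)


def with_seed(config: StudyConfig, seed: int) -> StudyConfig:
    return replace(config, seed=seed)
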