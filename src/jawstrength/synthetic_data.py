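"""Synthetic study generator.

Produces a complete eight-population study with the statistical structure
the analysis assumes, so the whole pipeline runs and is testable without
any download: field-measured specimens with bite forces, alcohol-preserved
specimens with shrunken measurements and 3D landmark sets in both regimes,
a watertight reference jaw mesh with its landmark configuration, and a
per-population lever table.

The template jaw is a stylised left mandible: a convex tapered wedge,
12 mm long, deeper and wider posteriorly.  Population mean shapes are the
template under smooth low-frequency deformation fields (a small random
affine map plus a long-wavelength dorsoventral bow and a population depth
factor), individuals are the mean plus isotropic Gaussian landmark noise,
and bite forces follow log(bite) = a + b*log(SVL) + eps with Gaussian eps
on the log scale.  Alcohol specimens get per-measurement shrinkage factors
(SVL most affected, PL least).  Default sample sizes are the study's
(fieldwork 229, alcohol 74 across the eight islets).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .core_io import (
    DEFAULT_MUSCLE_WEIGHTS,
    DEFAULT_POPULATIONS,
    DegenerateInputError,
    LandmarkSet,
    SpecimenRecord,
    SurfaceMesh,
    write_landmarks,
    write_mesh,
    write_specimen_table,
)
from .mechanical_advantage import default_muscles, measure_levers

__all__ = [
    "GeneratorParams",
    "StudyBundle",
    "generate_study",
    "generate_fixture",
    "template_mandible_landmarks",
    "template_dentary_landmarks",
    "template_jaw_mesh",
    "jaw_muscle_geometry",
    "HINGE_LANDMARK",
    "BITE_LANDMARK",
]

# template dimensions (mm)
JAW_LENGTH = 12.0
DEPTH_ANT, DEPTH_POST = 1.2, 3.0
WIDTH_ANT, WIDTH_POST = 0.6, 1.6
DENTARY_LENGTH = 7.0

#: landmark roles in the 16-point mandible regime
ANTERIOR_LANDMARK = 0  # most anterior point (landmark 1)
DORSAL_LANDMARK = 1  # coronoid-region dorsal point
HINGE_LANDMARK = 2  # most posterior point / articulation (landmark 3)
BITE_LANDMARK = 3  # apex of the 10th tooth (~1/3 along the tooth row)

# fieldwork / alcohol / male-alcohol sample sizes per islet (study defaults)
DEFAULT_N_FIELD = (50, 57, 21, 23, 21, 28, 19, 10)
DEFAULT_N_FIELD_MALE = (30, 29, 16, 13, 10, 14, 12, 8)
DEFAULT_N_ALCOHOL = (10, 11, 5, 9, 10, 9, 10, 10)
DEFAULT_N_ALCOHOL_MALE = (5, 8, 3, 5, 3, 5, 4, 5)
DEFAULT_YEARS = (1931, 1942, 1950, 1957, 1960, 1965, 1972, 1980)

#: multiplicative shrinkage of alcohol-preserved measurements
#: (SVL most affected, PL least)
DEFAULT_SHRINKAGE = {"svl": 0.93, "hh": 0.95, "pl": 0.995, "pw": 0.96, "mw": 0.95}

#: baseline linear measurements (mm) at size factor 1
BASE_MEASUREMENTS = {"svl": 60.0, "hh": 10.0, "pl": 12.0, "pw": 9.0, "mw": 7.0}


def _depth(x: np.ndarray) -> np.ndarray:
    return DEPTH_ANT + (DEPTH_POST - DEPTH_ANT) * x / JAW_LENGTH


def _width(x: np.ndarray) -> np.ndarray:
    return WIDTH_ANT + (WIDTH_POST - WIDTH_ANT) * x / JAW_LENGTH


def _on_wedge(x: float, fy: float, fz: float) -> np.ndarray:
    """Point on/in the template wedge: fy, fz in [-1, 1] span depth/width."""
    return np.array([x, 0.5 * fy * _depth(np.array(x)), 0.5 * fz * _width(np.array(x))])


_MANDIBLE16_PARAM = [
    (0.0, 0.0, 0.0),  # 0 anterior tip
    (8.0, 1.0, 0.0),  # 1 dorsal, coronoid region
    (12.0, 0.0, 0.0),  # 2 articular (hinge)
    (4.0, 1.0, 0.0),  # 3 bite point (10th tooth apex)
    (2.0, -1.0, 0.0),
    (6.0, -1.0, 0.0),
    (10.0, -1.0, 0.0),
    (12.0, 1.0, 0.0),
    (3.0, 1.0, 1.0),
    (9.0, 0.0, 1.0),
    (6.0, 0.0, -1.0),
    (12.0, -1.0, 1.0),
    (1.0, 0.0, 1.0),
    (5.0, 0.5, -1.0),
    (10.5, 1.0, 0.0),
    (7.0, -0.5, 1.0),
]

# fixed dentary landmarks sit on distinct anatomical loci, deliberately off
# the four sampled curves so no TPS control point is duplicated
_DENTARY7_PARAM = [
    (0.0, 0.0, 0.0),  # anterior tip
    (4.0, 1.0, -0.6),  # tooth-row dorsolabial (bite region)
    (7.0, 1.0, 0.5),  # posterodorsal cut corner, lingual
    (7.0, -1.0, -0.5),  # posteroventral cut corner, labial
    (3.5, -1.0, 0.5),  # ventral margin, lingual
    (1.0, 0.5, 1.0),  # symphysis region, dorsolingual
    (5.0, -0.5, -1.0),  # labial face, ventral
]


def template_mandible_landmarks() -> np.ndarray:
    return np.array([_on_wedge(*p) for p in _MANDIBLE16_PARAM])


def template_dentary_landmarks(points_per_curve: int = 40):
    """Template dentary fixed landmarks and four high-density curves."""
    fixed = np.array([_on_wedge(*p) for p in _DENTARY7_PARAM])
    t = np.linspace(0.0, DENTARY_LENGTH, points_per_curve)
    curves = (
        np.column_stack([t, 0.5 * _depth(t), np.zeros_like(t)]),  # dorsal margin
        np.column_stack([t, -0.5 * _depth(t), np.zeros_like(t)]),  # ventral margin
        np.column_stack([t, np.zeros_like(t), 0.5 * _width(t)]),  # lingual line
        np.column_stack([t, np.zeros_like(t), -0.5 * _width(t)]),  # labial line
    )
    return fixed, curves


def template_jaw_mesh(bone: str = "mandible", max_edge: float = 0.8) -> SurfaceMesh:
    """Watertight convex wedge mesh for the template jaw (mm)."""
    L = JAW_LENGTH if bone == "mandible" else DENTARY_LENGTH
    box = trimesh.creation.box(extents=(L, 1.0, 1.0))
    # the y/z taper stretches edges by up to depth/width factors (~3x), so
    # subdivide the unit box finer to end near the requested edge length
    v, f = trimesh.remesh.subdivide_to_size(
        box.vertices, box.faces, max_edge=max_edge / 3.0
    )
    v = np.asarray(v, dtype=float)
    v[:, 0] += L / 2.0  # x in [0, L]
    v[:, 1] *= _depth(v[:, 0])
    v[:, 2] *= _width(v[:, 0])
    return SurfaceMesh(v, np.asarray(f))


def jaw_muscle_geometry(landmarks16: np.ndarray):
    """Muscle insertion points and lines of action for a mandible
    configuration, expressed through the template's landmark roles."""
    lm = np.asarray(landmarks16, dtype=float)
    insertions = {
        "adductor_combined": lm[14],  # posterior coronoid crest, near the joint
        "pseudotemporalis": lm[9],  # lingual coronoid region
        "pterygoideus_external": lm[6],
        "pterygoideus_internal": lm[11],
    }
    lines = {
        "adductor_combined": np.array([0.29, 0.96, 0.0]),
        "pseudotemporalis": np.array([0.10, 0.97, 0.20]),
        "pterygoideus_external": np.array([0.45, 0.85, -0.25]),
        "pterygoideus_internal": np.array([0.40, 0.80, 0.45]),
    }
    return insertions, lines


# ---------------------------------------------------------------------------
# Parameters and bundle
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    n_field: tuple[int, ...] = DEFAULT_N_FIELD
    n_field_male: tuple[int, ...] = DEFAULT_N_FIELD_MALE
    n_alcohol: tuple[int, ...] = DEFAULT_N_ALCOHOL
    n_alcohol_male: tuple[int, ...] = DEFAULT_N_ALCOHOL_MALE
    collection_years: tuple[int, ...] = DEFAULT_YEARS
    shrinkage: dict = field(default_factory=lambda: dict(DEFAULT_SHRINKAGE))
    shape_effect_sd: float = 0.03  # population deformation coefficient scale
    depth_effects: tuple[float, ...] | None = None  # optional injected ordering
    landmark_noise_sd: float = 0.02  # mm, isotropic per landmark
    size_sd: float = 0.06  # log-scale individual size spread
    pop_size_sd: float = 0.05  # log-scale population mean size spread
    measurement_noise_sd: float = 0.02  # log scale
    allometry_intercept: float = float(np.log(10.0) - 2.0 * np.log(60.0))
    allometry_slope: float = 2.0
    bite_noise_sd: float = 0.15  # log scale
    male_size_boost: float = 0.08  # males are larger on the log scale
    seed: int = 1

    def __post_init__(self) -> None:
        k = len(self.populations)
        for name in ("n_field", "n_field_male", "n_alcohol", "n_alcohol_male",
                     "collection_years"):
            if len(getattr(self, name)) != k:
                raise DegenerateInputError(f"{name} must have {k} entries")
        for v in self.shrinkage.values():
            if not (0 < v <= 1.2):
                raise DegenerateInputError("shrinkage factors must be in (0, 1.2]")
        for s in (self.shape_effect_sd, self.landmark_noise_sd, self.size_sd,
                  self.measurement_noise_sd, self.bite_noise_sd):
            if s < 0:
                raise DegenerateInputError("all sds must be >= 0")


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    params: GeneratorParams
    records: list[SpecimenRecord]
    mandible_sets: list[LandmarkSet]
    dentary_sets: list[LandmarkSet]
    specimen_meta: pd.DataFrame  # id, population, sex for landmark sets
    reference_mandible: SurfaceMesh
    reference_dentary: SurfaceMesh
    reference_mandible_landmarks: np.ndarray
    reference_dentary_landmarks: LandmarkSet
    lever_table: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "landmarks" / "mandible").mkdir(parents=True, exist_ok=True)
        (out / "landmarks" / "dentary").mkdir(parents=True, exist_ok=True)
        write_specimen_table(self.records, out / "specimens.csv")
        for ls in self.mandible_sets:
            write_landmarks(ls, out / "landmarks" / "mandible" / f"{ls.specimen_id}.nts")
        for ls in self.dentary_sets:
            write_landmarks(ls, out / "landmarks" / "dentary" / f"{ls.specimen_id}.nts")
        write_mesh(self.reference_mandible, out / "reference_mandible.ply")
        write_mesh(self.reference_dentary, out / "reference_dentary.ply")
        np.savetxt(
            out / "reference_mandible_landmarks.txt",
            self.reference_mandible_landmarks,
        )
        write_landmarks(self.reference_dentary_landmarks, out / "reference_dentary.nts")
        self.lever_table.to_csv(out / "levers.csv", index=False)
        self.specimen_meta.to_csv(out / "landmark_specimens.csv", index=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _population_deformation(rng: np.random.Generator, params: GeneratorParams,
                            depth_effect: float):
    """A smooth deformation of template space: small random affine map plus a
    long-wavelength dorsoventral bow, plus a depth (corpus thickness) factor."""
    s = params.shape_effect_sd
    A = np.eye(3) + s * rng.normal(size=(3, 3))
    bow = s * rng.normal()  # dorsoventral bow amplitude (relative)
    center = np.array([JAW_LENGTH / 2, 0.0, 0.0])

    def deform(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - center
        out = p @ A.T
        out[:, 1] *= 1.0 + depth_effect
        out[:, 1] += bow * JAW_LENGTH * np.sin(np.pi * (p[:, 0] / JAW_LENGTH + 0.5))
        return out + center

    return deform


def generate_study(params: GeneratorParams | None = None) -> StudyBundle:
    """Generate the full synthetic study (deterministic given the seed)."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    n_pop = len(params.populations)
    if params.depth_effects is not None:
        depth_effects = np.asarray(params.depth_effects, dtype=float)
    else:
        depth_effects = params.shape_effect_sd * rng.normal(size=n_pop)
    pop_size = params.pop_size_sd * rng.normal(size=n_pop)  # log scale
    deforms = [
        _population_deformation(rng, params, depth_effects[i]) for i in range(n_pop)
    ]

    lm16_t = template_mandible_landmarks()
    dent_fixed_t, dent_curves_t = template_dentary_landmarks()

    records: list[SpecimenRecord] = []
    mandible_sets: list[LandmarkSet] = []
    dentary_sets: list[LandmarkSet] = []
    meta_rows = []

    def measurements(log_size: float) -> dict:
        out = {}
        for name, base in BASE_MEASUREMENTS.items():
            noise = params.measurement_noise_sd * rng.normal()
            out[name] = base * np.exp(log_size + noise)
        return out

    for i, pop in enumerate(params.populations):
        # fieldwork animals: measurements + bite force
        n_f, n_fm = params.n_field[i], params.n_field_male[i]
        for j in range(n_f):
            sex = "male" if j < n_fm else "female"
            log_size = (
                pop_size[i]
                + (params.male_size_boost if sex == "male" else 0.0)
                + params.size_sd * rng.normal()
            )
            m = measurements(log_size)
            # bite is log-linear in the measured SVL (the size a fieldworker
            # would record), with log-normal scatter
            log_bite = (
                params.allometry_intercept
                + params.allometry_slope * np.log(m["svl"])
                + params.bite_noise_sd * rng.normal()
            )
            records.append(
                SpecimenRecord(
                    specimen_id=f"F_{i}_{j}",
                    population=pop,
                    sex=sex,
                    method="fieldwork",
                    bite_force=float(np.exp(log_bite)),
                    **m,
                )
            )
        # alcohol specimens: shrunken measurements + landmarks
        n_a, n_am = params.n_alcohol[i], params.n_alcohol_male[i]
        for j in range(n_a):
            sex = "male" if j < n_am else "female"
            log_size = (
                pop_size[i]
                + (params.male_size_boost if sex == "male" else 0.0)
                + params.size_sd * rng.normal()
            )
            m = measurements(log_size)
            m = {k: v * params.shrinkage[k] for k, v in m.items()}
            sid = f"A_{i}_{j}"
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    population=pop,
                    sex=sex,
                    method="alcohol",
                    collection_year=params.collection_years[i],
                    **m,
                )
            )
            scale = np.exp(log_size)
            d = deforms[i]
            lm16 = scale * d(lm16_t)
            lm16 += params.landmark_noise_sd * rng.normal(size=lm16.shape)
            mandible_sets.append(LandmarkSet(sid, "mandible16", lm16))
            fixed = scale * d(dent_fixed_t)
            fixed += params.landmark_noise_sd * rng.normal(size=fixed.shape)
            curves = []
            for c in dent_curves_t:
                cc = scale * d(c)
                # noise shared along each curve endpoint-consistently is not
                # needed; semilandmarks are resampled, anchors keep noise
                cc += params.landmark_noise_sd * rng.normal(size=cc.shape)
                curves.append(cc)
            dentary_sets.append(LandmarkSet(sid, "dentary_curves", fixed, tuple(curves)))
            meta_rows.append({"specimen_id": sid, "population": pop, "sex": sex})

    # per-population lever table from the population-mean mandible geometry
    lever_rows = []
    for i, pop in enumerate(params.populations):
        lm = np.exp(pop_size[i]) * deforms[i](lm16_t)
        ins, lines = jaw_muscle_geometry(lm)
        muscles = default_muscles(ins, lines)
        levers = measure_levers(lm[HINGE_LANDMARK], lm[BITE_LANDMARK], muscles)
        for name in levers.in_levers:
            lever_rows.append(
                {
                    "population": pop,
                    "muscle": name,
                    "in_lever": levers.in_levers[name],
                    "out_lever": levers.out_levers[name],
                }
            )

    bundle = StudyBundle(
        params=params,
        records=records,
        mandible_sets=mandible_sets,
        dentary_sets=dentary_sets,
        specimen_meta=pd.DataFrame(
            meta_rows, columns=["specimen_id", "population", "sex"]
        ),
        reference_mandible=template_jaw_mesh("mandible"),
        reference_dentary=template_jaw_mesh("dentary"),
        reference_mandible_landmarks=lm16_t,
        reference_dentary_landmarks=LandmarkSet(
            "reference", "dentary_curves", dent_fixed_t, dent_curves_t
        ),
        lever_table=pd.DataFrame(lever_rows),
        truth={
            "allometry_intercept": params.allometry_intercept,
            "allometry_slope": params.allometry_slope,
            "depth_effects": depth_effects.tolist(),
            "pop_log_size": pop_size.tolist(),
            "shrinkage": dict(params.shrinkage),
        },
    )
    return bundle


# ---------------------------------------------------------------------------
# Analytic fixtures for warping / FE tests
# ---------------------------------------------------------------------------


def generate_fixture(name: str):
    """Deterministic parametric meshes with closed-form reference values.

    Returns ``(mesh, refs)`` (or ``((mesh_a, mesh_b), refs)`` for
    ``two_jaws``).
    """
    if name == "cube":
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces)), {
            "volume": 1.0
        }
    if name in ("bar", "cantilever"):
        L, b, h = 10.0, 1.0, 1.0
        box = trimesh.creation.box(extents=(L, h, b))
        box.apply_translation((L / 2, 0, 0))
        mesh = SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        I = b * h**3 / 12.0
        refs = {
            "volume": L * b * h,
            "length": L,
            "area": b * h,
            "second_moment": I,
            "tip_deflection": lambda F, E: F * L**3 / (3.0 * E * I),
            "axial_displacement": lambda F, E: F * L / (E * b * h),
        }
        return mesh, refs
    if name == "sphere":
        r = 1.0
        ico = trimesh.creation.icosphere(subdivisions=4, radius=r)
        return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces)), {
            "volume": 4.0 / 3.0 * np.pi * r**3,
            "radius": r,
        }
    if name == "two_jaws":
        thick = template_jaw_mesh("dentary")
        thin = SurfaceMesh(thick.vertices.copy(), thick.faces.copy())
        v = thin.vertices.copy()
        v[:, 1] *= 0.6  # thinned corpus
        thin = SurfaceMesh(v, thin.faces)
        return (thick, thin), {"thicker_first": True}
    raise DegenerateInputError(f"unknown fixture {name!r}")
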