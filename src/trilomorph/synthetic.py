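"""Parametric generator of cephalon-like outlines and group-structured datasets.

The shape model is deliberately low-dimensional — seven parameters — so that
ground-truth group structure is known exactly and recoverable downstream.  It
is an abstraction of the shape factors that separate real cephalic outlines
(axial length relative to width, genal-spine length / base width / direction,
marginal brim, anterior-margin roundness), NOT an anatomical model of any
trilobite.

Geometry (width W along x, anterior up):
  * an anterior dome through the posterior corners (+-W/2, 0), a superellipse
    of height L*W whose exponent is blended by roundness r between an ellipse
    (r=1) and a flatter, box-like profile (r=0);
  * an optional brim: a normal-direction bulge of the dome, maximal at the
    apex and vanishing at the corners, of magnitude b*W;
  * two triangular genal spines hanging from the posterior corners, tip at
    corner + s*W in the direction theta (measured from straight posterior
    toward lateral), base width w*W along the posterior margin;
  * a straight posterior margin connecting the spine bases.

Each specimen is emitted as the two open digitization curves (anterior: left
spine tip over the front to the right tip; posterior: right tip along the
rear to the left tip), jittered radially, resampled to 64 points each and
assembled through the standard outline pipeline — so synthetic data exercise
the exact code path real digitizations take.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from trilomorph.io_tps import RawSpecimenRecord, SpecimenMetadata
from trilomorph.outline import ClosedOutline, assemble_outline, is_simple_polygon, resample_curve

_DENSE = 160  # dense boundary samples per curve before jitter/resampling


class InvalidParamsError(ValueError):
    pass


@dataclass(frozen=True)
class CephalonParams:
    """Seven-parameter cephalon shape.

    width: overall width W (arbitrary units; size is normalized away later).
    axial_length_ratio: dome height / width (sagittal proportion), > 0.
    spine_length: genal spine length as a fraction of W, >= 0.
    spine_base_width: spine base as a fraction of W, in (0, 0.5).
    spine_angle: radians from straight posterior toward lateral, in [0, pi/2).
    brim_width: marginal brim bulge as a fraction of W, >= 0.
    roundness: anterior-margin curvature blend in [0, 1] (1 = elliptical).
    """

    width: float = 1.0
    axial_length_ratio: float = 0.6
    spine_length: float = 0.25
    spine_base_width: float = 0.10
    spine_angle: float = 0.35
    brim_width: float = 0.0
    roundness: float = 0.9

    def validate(self) -> None:
        if self.width <= 0:
            raise InvalidParamsError("width must be positive")
        if self.axial_length_ratio <= 0:
            raise InvalidParamsError("axial_length_ratio must be positive")
        if self.spine_length < 0:
            raise InvalidParamsError("spine_length must be nonnegative")
        if not 0 < self.spine_base_width < 0.5:
            raise InvalidParamsError("spine_base_width must be in (0, 0.5)")
        if not 0 <= self.spine_angle < np.pi / 2:
            raise InvalidParamsError("spine_angle must be in [0, pi/2)")
        if self.brim_width < 0:
            raise InvalidParamsError("brim_width must be nonnegative")
        if not 0 <= self.roundness <= 1:
            raise InvalidParamsError("roundness must be in [0, 1]")


#: documented valid sampling ranges; truncated sampling keeps parameters here
PARAM_RANGES = {
    "axial_length_ratio": (0.25, 1.2),
    "spine_length": (0.0, 0.7),
    "spine_base_width": (0.02, 0.30),
    "spine_angle": (0.0, 1.2),
    "brim_width": (0.0, 0.30),
    "roundness": (0.2, 1.0),
}


@dataclass
class PopulationSpec:
    """A group of specimens drawn around a mean parameter vector.

    ``param_sd`` maps parameter names to Gaussian spreads (truncated to the
    documented valid ranges); ``noise_sd`` is the radial outline jitter as a
    fraction of W, emulating digitization and preservation noise.
    """

    group_label: str
    n: int
    mean_params: CephalonParams
    param_sd: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.004
    period_label: str = "Ordovician"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParamsError("population size must be >= 1")
        self.mean_params.validate()


def _dome(params: CephalonParams, n: int) -> np.ndarray:
    """Anterior dome from (-W/2, 0) over the apex to (+W/2, 0), with brim."""
    W = params.width
    H = params.axial_length_ratio * W
    # exponent 2 (ellipse) at r=1, up to 4 (flat-topped) at r=0
    m = 2.0 + 2.0 * (1.0 - params.roundness)
    phi = np.linspace(np.pi, 0.0, n)  # left corner -> apex -> right corner
    cx, sy = np.cos(phi), np.sin(phi)
    x = 0.5 * W * np.sign(cx) * np.abs(cx) ** (2.0 / m)
    y = H * np.abs(sy) ** (2.0 / m)
    pts = np.column_stack([x, y])
    if params.brim_width > 0:
        # posterolateral flare: the bulge is maximal at the dome shoulders
        # and vanishes at the apex and the spine-base corners, giving the
        # broad horseshoe-like margin of brimmed cephala
        tangent = np.gradient(pts, axis=0)
        tnorm = np.linalg.norm(tangent, axis=1, keepdims=True)
        normal = np.column_stack([tangent[:, 1], -tangent[:, 0]]) / tnorm
        bulge = params.brim_width * W * np.abs(np.sin(2 * phi))[:, None]
        pts = pts + normal * bulge
        pts[0] = (-0.5 * W, 0.0)
        pts[-1] = (0.5 * W, 0.0)
    return pts


def _spine_tip(params: CephalonParams, side: int) -> np.ndarray:
    """Spine tip for side=-1 (left) or +1 (right)."""
    W = params.width
    corner = np.array([side * 0.5 * W, 0.0])
    direction = np.array([side * np.sin(params.spine_angle), -np.cos(params.spine_angle)])
    return corner + params.spine_length * W * direction


def _segment(p0: np.ndarray, p1: np.ndarray, n: int, include_start: bool) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0[None, :] * (1 - t) + p1[None, :] * t
    return pts if include_start else pts[1:]


def cephalon_curves(params: CephalonParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free dense anterior and posterior digitization curves."""
    params.validate()
    W = params.width
    tip_l = _spine_tip(params, -1)
    tip_r = _spine_tip(params, +1)
    corner_l = np.array([-0.5 * W, 0.0])
    corner_r = np.array([+0.5 * W, 0.0])
    base_l = np.array([-0.5 * W + params.spine_base_width * W, 0.0])
    base_r = np.array([+0.5 * W - params.spine_base_width * W, 0.0])

    n_spine = max(8, _DENSE // 8)
    dome = _dome(params, _DENSE)
    if params.spine_length > 0:
        anterior = np.vstack(
            [
                _segment(tip_l, corner_l, n_spine, include_start=True),
                dome[1:],
                _segment(corner_r, tip_r, n_spine, include_start=False),
            ]
        )
        posterior = np.vstack(
            [
                _segment(tip_r, base_r, n_spine, include_start=True),
                _segment(base_r, base_l, _DENSE // 2, include_start=False),
                _segment(base_l, tip_l, n_spine, include_start=False),
            ]
        )
    else:
        # spines collapsed: curves anchor at the posterior corners
        anterior = dome
        posterior = _segment(corner_r, corner_l, _DENSE // 2, include_start=True)
    return anterior, posterior


def _jitter(curve: np.ndarray, centre: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Radial Gaussian jitter about ``centre``; endpoints stay fixed."""
    if sd <= 0:
        return curve
    out = curve.copy()
    radial = out[1:-1] - centre
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out[1:-1] += (radial / norms) * rng.normal(0.0, sd, size=(len(out) - 2, 1))
    return out


def generate_cephalon(
    params: CephalonParams,
    n_points: int = 128,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    max_attempts: int = 100,
) -> ClosedOutline:
    """Generate one closed cephalon outline through the standard pipeline.

    The parametric boundary is sampled as the two digitization curves, jitter
    is applied before resampling, each curve is resampled to 64 points, and
    the pair is assembled into a 128-point positively wound outline.  Jitter
    draws that self-intersect are rejected (up to ``max_attempts``).
    """
    if n_points != 128:
        raise ValueError("the digitization protocol fixes outlines at 128 points")
    params.validate()
    rng = rng or np.random.default_rng()
    anterior, posterior = cephalon_curves(params)
    centre = np.vstack([anterior, posterior]).mean(axis=0)
    sd = noise_sd * params.width
    for _ in range(max_attempts):
        a = _jitter(anterior, centre, sd, rng)
        p = _jitter(posterior, centre, sd, rng)
        outline = assemble_outline(resample_curve(a, 64), resample_curve(p, 64))
        if is_simple_polygon(outline.points):
            return outline
        if sd == 0:
            break
    raise InvalidParamsError(
        f"could not produce a simple polygon in {max_attempts} attempts "
        f"(params={params}, noise_sd={noise_sd})"
    )


def sample_params(
    mean: CephalonParams,
    sd: dict[str, float],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> CephalonParams:
    """Truncated-Gaussian parameter draw around ``mean`` within PARAM_RANGES."""
    values = {}
    for name, (lo, hi) in PARAM_RANGES.items():
        mu = getattr(mean, name)
        sigma = sd.get(name, 0.0)
        if sigma <= 0:
            values[name] = float(np.clip(mu, lo, hi))
            continue
        for _ in range(max_attempts):
            v = rng.normal(mu, sigma)
            if lo <= v <= hi:
                break
        else:
            v = float(np.clip(mu, lo, hi))
        values[name] = float(v)
    return replace(mean, **values)


def generate_dataset(
    specs: Sequence[PopulationSpec],
    seed: int = 0,
) -> tuple[list[RawSpecimenRecord], list[SpecimenMetadata], list[ClosedOutline]]:
    """Generate all specimens of a multi-group dataset.

    Returns the raw two-curve records (as a TPS reader would produce), the
    metadata rows, and the assembled outlines, in matching order.  All
    randomness flows from ``seed`` (per-spec seeds override their stream).
    """
    if not specs:
        raise ValueError("need at least one population spec")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(specs))
    records: list[RawSpecimenRecord] = []
    metadata: list[SpecimenMetadata] = []
    outlines: list[ClosedOutline] = []
    for spec, stream in zip(specs, streams):
        rng = np.random.default_rng(spec.seed if spec.seed is not None else stream)
        for i in range(spec.n):
            params = sample_params(spec.mean_params, spec.param_sd, rng)
            anterior, posterior = cephalon_curves(params)
            centre = np.vstack([anterior, posterior]).mean(axis=0)
            sd = spec.noise_sd * params.width
            outline = None
            for _ in range(100):
                a = _jitter(anterior, centre, sd, rng)
                p = _jitter(posterior, centre, sd, rng)
                cand = assemble_outline(resample_curve(a, 64), resample_curve(p, 64))
                if is_simple_polygon(cand.points):
                    outline = cand
                    record_curves = [resample_curve(a, 64), resample_curve(p, 64)]
                    break
            if outline is None:
                raise InvalidParamsError(
                    f"group {spec.group_label!r}: jitter never produced a simple polygon"
                )
            sid = f"{spec.group_label}_{spec.period_label}_{i:04d}"
            records.append(RawSpecimenRecord(id=sid, curves=record_curves))
            metadata.append(
                SpecimenMetadata(
                    id=sid,
                    species=f"synthetic_{spec.group_label.lower()}_{i:04d}",
                    order_label=spec.group_label,
                    period_label=spec.period_label,
                )
            )
            outlines.append(outline)
    return records, metadata, outlines


# --------------------------------------------------------------------------
# presets

_MID = CephalonParams(axial_length_ratio=0.62, spine_length=0.22, spine_base_width=0.10,
                      spine_angle=0.35, brim_width=0.0, roundness=0.9)
_SD_NARROW = {"axial_length_ratio": 0.09, "spine_length": 0.09,
              "spine_base_width": 0.03, "spine_angle": 0.15, "roundness": 0.12}
_SD_WIDE = {"axial_length_ratio": 0.16, "spine_length": 0.16,
            "spine_base_width": 0.05, "spine_angle": 0.25, "roundness": 0.20}

#: order-level mean shapes for the study-scale preset, keyed to the
#: qualitative contrasts seen in real cephala: harpids long with broad brims
#: and broad genal projections, trinucleids similar but with narrow distally
#: directed spines, lichids/odontopleurids axially short, an
#: aulacopleurid-olenid-redlichiid morphogroup, and an asaphid-corynexochid-
#: phacopid-proetid-unassigned central morphogroup.
ORDER_MEANS: dict[str, CephalonParams] = {
    "Harpida": CephalonParams(axial_length_ratio=0.95, spine_length=0.50,
                              spine_base_width=0.20, spine_angle=0.45,
                              brim_width=0.22, roundness=0.85),
    "Trinucleida": CephalonParams(axial_length_ratio=0.70, spine_length=0.45,
                                  spine_base_width=0.04, spine_angle=0.15,
                                  brim_width=0.06, roundness=0.85),
    "Lichida": CephalonParams(axial_length_ratio=0.45, spine_length=0.18,
                              spine_base_width=0.10, spine_angle=0.40,
                              roundness=0.75),
    "Odontopleurida": CephalonParams(axial_length_ratio=0.46, spine_length=0.20,
                                     spine_base_width=0.10, spine_angle=0.42,
                                     roundness=0.75),
    "Aulacopleurida": CephalonParams(axial_length_ratio=0.60, spine_length=0.30,
                                     spine_base_width=0.10, spine_angle=0.35,
                                     roundness=0.9),
    "Olenida": CephalonParams(axial_length_ratio=0.60, spine_length=0.31,
                              spine_base_width=0.10, spine_angle=0.35,
                              roundness=0.9),
    "Redlichiida": CephalonParams(axial_length_ratio=0.59, spine_length=0.30,
                                  spine_base_width=0.10, spine_angle=0.36,
                                  roundness=0.9),
    "Asaphida": replace(_MID, axial_length_ratio=0.63),
    "Corynexochida": replace(_MID, axial_length_ratio=0.64, spine_length=0.20),
    "Phacopida": replace(_MID, axial_length_ratio=0.61),
    "Proetida": replace(_MID, axial_length_ratio=0.66, spine_length=0.18),
    "Unassigned": _MID,
}

#: per-order specimen counts summing to 983 (proportional placeholders with
#: the documented qualitative structure: strongly unequal sizes, three orders
#: under 40 specimens, asaphids/phacopids/proetids large)
ORDER_COUNTS = {
    "Asaphida": 150, "Aulacopleurida": 35, "Corynexochida": 80, "Harpida": 60,
    "Lichida": 30, "Odontopleurida": 35, "Olenida": 70, "Phacopida": 180,
    "Proetida": 140, "Redlichiida": 75, "Trinucleida": 40, "Unassigned": 88,
}

#: stratigraphic ranges as per-period fractions of each order's sample;
#: redlichiids Cambrian-only, only proetids reach the Permian, only proetids
#: and aulacopleurids survive into the Carboniferous
ORDER_PERIOD_FRACTIONS: dict[str, dict[str, float]] = {
    "Redlichiida": {"Cambrian": 1.0},
    "Olenida": {"Cambrian": 0.6, "Ordovician": 0.4},
    "Asaphida": {"Cambrian": 0.35, "Ordovician": 0.65},
    "Unassigned": {"Cambrian": 0.7, "Ordovician": 0.3},
    "Corynexochida": {"Cambrian": 0.45, "Ordovician": 0.25, "Silurian": 0.15,
                      "Devonian": 0.15},
    "Harpida": {"Ordovician": 0.45, "Silurian": 0.25, "Devonian": 0.3},
    "Trinucleida": {"Ordovician": 0.85, "Silurian": 0.15},
    "Lichida": {"Ordovician": 0.4, "Silurian": 0.3, "Devonian": 0.3},
    "Odontopleurida": {"Ordovician": 0.4, "Silurian": 0.3, "Devonian": 0.3},
    "Phacopida": {"Ordovician": 0.35, "Silurian": 0.3, "Devonian": 0.35},
    "Aulacopleurida": {"Ordovician": 0.3, "Silurian": 0.25, "Devonian": 0.25,
                       "Carboniferous": 0.2},
    "Proetida": {"Ordovician": 0.2, "Silurian": 0.2, "Devonian": 0.3,
                 "Carboniferous": 0.2, "Permian": 0.1},
}


def _split_counts(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` across periods."""
    raw = {k: total * v for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return {k: v for k, v in counts.items() if v > 0}


def preset_study_mimic(noise_sd: float = 0.004) -> list[PopulationSpec]:
    """983 specimens across 12 orders and 6 periods, study-scale structure."""
    wide_orders = {"Asaphida", "Olenida", "Redlichiida", "Trinucleida"}
    specs = []
    for order, total in ORDER_COUNTS.items():
        sd = _SD_WIDE if order in wide_orders else _SD_NARROW
        for period, n in _split_counts(total, ORDER_PERIOD_FRACTIONS[order]).items():
            specs.append(
                PopulationSpec(
                    group_label=order,
                    n=n,
                    mean_params=ORDER_MEANS[order],
                    param_sd=dict(sd),
                    noise_sd=noise_sd,
                    period_label=period,
                )
            )
    return specs


def preset_five_morphogroups(n_per_group: int = 40, noise_sd: float = 0.004) -> list[PopulationSpec]:
    """Six orders realizing five morphogroups; the brimmed long-spined
    harpid analogue sits far from everything else in morphospace, and the
    three central orders are near-identical."""
    mid_sd = dict(_SD_NARROW)
    groups = [
        ("Harpida", ORDER_MEANS["Harpida"]),
        ("Trinucleida", ORDER_MEANS["Trinucleida"]),
        ("Lichida", ORDER_MEANS["Lichida"]),
        ("Asaphida", _MID),
        ("Phacopida", replace(_MID, axial_length_ratio=0.63)),
        ("Proetida", replace(_MID, spine_length=0.23)),
    ]
    return [
        PopulationSpec(group_label=name, n=n_per_group, mean_params=params,
                       param_sd=mid_sd, noise_sd=noise_sd)
        for name, params in groups
    ]


PRESETS = {
    "study_mimic": preset_study_mimic,
    "five_morphogroups": preset_five_morphogroups,
}
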