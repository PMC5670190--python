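"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three kinds of data the analysis consumes:

* bright-field-like micrographs of droplet monolayers (bright interior,
  darker ring edge, additive Gaussian noise) with a per-droplet truth table;
* hierarchical droplet-diameter tables (day / well / droplet variance
  components) mirroring a design of several wells per cartridge measured on
  consecutive days, one cartridge per day;
* binomial positive-partition counts for ddPCR reactions, the exact inverse
  model of the Poisson concentration estimator.

Default parameters are the study conditions of the droplet-generator
comparison this package analyses: droplet diameters near 111 um (sphere
volume ~0.715 nL) with ~2 um within-well SD, 6 wells x 3 days, and reaction
counts near 15,000 accepted partitions at a 100x dilution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quant import ReactionResult

__all__ = [
    "ImageSpec",
    "PlacementError",
    "generate_droplet_image",
    "HierarchicalDiameterSpec",
    "generate_hierarchical_diameters",
    "PartitionCountSpec",
    "generate_partition_counts",
    "generate_duplex_wells",
]


class PlacementError(RuntimeError):
    """Droplet placement failed: packing density infeasible within retries."""


@dataclass
class ImageSpec:
    """Ground-truth description of one synthetic micrograph.

    Either give explicit ``centers_px`` (x, y) and ``diameters_um`` — in
    which case droplets may intentionally touch or cross the frame edge —
    or give ``n_droplets`` plus a diameter distribution and placement is
    random without overlap.

    Intensities are grey levels on a 0–255 scale: a uniform background, a
    bright droplet interior, and a darker ring edge of ``ring_width_px``
    rendered *inside* the droplet boundary, so the true droplet disk is
    exactly the region deviating from the background.  Edges are
    anti-aliased with linear coverage.
    """

    shape: tuple[int, int] = (1200, 1200)  # (rows, cols)
    pixel_size_um: float = 0.5
    n_droplets: int = 0
    mean_diameter_um: float = 111.0
    sd_diameter_um: float = 2.0
    centers_px: Sequence[tuple[float, float]] | None = None  # (x, y)
    diameters_um: Sequence[float] | None = None
    noise_sd: float = 0.0  # grey levels
    ring_width_px: float = 3.0
    background: float = 90.0
    interior: float = 190.0
    ring: float = 40.0
    min_gap_px: float = 4.0
    allow_border: bool = False
    max_place_attempts: int = 5000

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.diameters_um is not None and np.any(np.asarray(self.diameters_um) <= 0):
            raise ValueError("true diameters must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _place_droplets(spec: ImageSpec, radii_px: np.ndarray, rng: np.random.Generator):
    h, w = spec.shape
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        lo_x, hi_x = r + 1, w - r - 1
        lo_y, hi_y = r + 1, h - r - 1
        if hi_x <= lo_x or hi_y <= lo_y:
            raise PlacementError(f"droplet of radius {r:.0f}px does not fit in frame {spec.shape}")
        for _ in range(spec.max_place_attempts):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            ok = all(
                np.hypot(x - cx, y - cy) > r + radii_px[j] + spec.min_gap_px
                for j, (cx, cy) in enumerate(centers)
            )
            if ok:
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place droplet {i + 1}/{len(radii_px)} after "
                f"{spec.max_place_attempts} attempts; reduce density or enlarge the frame"
            )
    return centers


def _render_droplet(img: np.ndarray, cx: float, cy: float, r_px: float, spec: ImageSpec) -> None:
    h, w = img.shape
    x0 = max(int(np.floor(cx - r_px)) - 2, 0)
    x1 = min(int(np.ceil(cx + r_px)) + 3, w)
    y0 = max(int(np.floor(cy - r_px)) - 2, 0)
    y1 = min(int(np.ceil(cy + r_px)) + 3, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    outer = np.clip(r_px - dist + 0.5, 0.0, 1.0)  # coverage of the droplet disk
    inner = np.clip(r_px - spec.ring_width_px - dist + 0.5, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += outer * (spec.ring - spec.background) + inner * (spec.interior - spec.ring)


def generate_droplet_image(spec: ImageSpec, seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one synthetic monolayer micrograph plus its ground-truth table.

    Returns ``(image, truth)`` where ``image`` is float32 grey levels and
    ``truth`` has columns droplet_id, center_x_px, center_y_px, diameter_um,
    border_touching.  Zero droplets yield a uniform-background frame and an
    empty table.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape

    if spec.centers_px is not None:
        if spec.diameters_um is None:
            raise ValueError("explicit centers require explicit diameters")
        centers = [tuple(map(float, c)) for c in spec.centers_px]
        diameters = np.asarray(spec.diameters_um, dtype=float)
        if len(centers) != diameters.size:
            raise ValueError("centers and diameters must match in length")
    else:
        n = spec.n_droplets
        if spec.diameters_um is not None:
            diameters = np.asarray(spec.diameters_um, dtype=float)
            n = diameters.size
        else:
            diameters = rng.normal(spec.mean_diameter_um, spec.sd_diameter_um, size=n)
            diameters = np.clip(diameters, 1e-3, None)
        centers = _place_droplets(spec, diameters / (2.0 * spec.pixel_size_um), rng)

    if np.any(diameters <= 0):
        raise ValueError("true diameters must be strictly positive")

    img = np.full(spec.shape, spec.background, dtype=np.float64)
    radii_px = diameters / (2.0 * spec.pixel_size_um)
    border = np.zeros(len(centers), dtype=bool)
    for i, ((cx, cy), r) in enumerate(zip(centers, radii_px)):
        border[i] = cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1
        _render_droplet(img, cx, cy, r, spec)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0).astype(np.float32)

    truth = pd.DataFrame(
        {
            "droplet_id": np.arange(len(centers)),
            "center_x_px": [c[0] for c in centers],
            "center_y_px": [c[1] for c in centers],
            "diameter_um": diameters,
            "border_touching": border,
        }
    )
    return img, truth


@dataclass
class HierarchicalDiameterSpec:
    """Variance-component layout of a multi-day droplet-sizing experiment.

    Diameters decompose as grand mean + day effect + well effect + droplet
    noise, all normal.  One cartridge is analysed per day, so the cartridge
    label coincides with the day.  The defaults emulate the droplet-generator
    comparison study: ~111 um droplets (sphere volume 0.715 nL), 2 um
    within-well droplet SD (≈0.04 nL at the volume scale), and well/day
    effects calibrated so the day-mean volumes spread by ~0.011 nL, the
    observed day-to-day variation of the study; 6 wells x 3 days x 172
    droplets per well (~3100 droplets in total).
    """

    mean_diameter_um: float = 110.94
    within_well_sd_um: float = 2.0
    between_well_sd_um: float = 1.0
    between_day_sd_um: float = 0.36
    wells_per_day: int = 6
    days: int = 3
    droplets_per_well: int = 172

    def __post_init__(self) -> None:
        if min(self.within_well_sd_um, self.between_well_sd_um, self.between_day_sd_um) < 0:
            raise ValueError("all SDs must be non-negative")
        if self.wells_per_day < 2 or self.days < 2:
            raise ValueError("need >= 2 wells per day and >= 2 days")
        if self.droplets_per_well < 1:
            raise ValueError("need >= 1 droplet per well")


def generate_hierarchical_diameters(
    spec: HierarchicalDiameterSpec, seed: int = 0
) -> pd.DataFrame:
    """Draw a droplet-diameter table with the spec's variance structure.

    Columns: droplet_id, well, cartridge, day, diameter_um.  Reproducible
    under a fixed seed; with all SDs zero every diameter equals the grand
    mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    droplet_id = 0
    for day in range(1, spec.days + 1):
        day_eff = rng.normal(0.0, spec.between_day_sd_um) if spec.between_day_sd_um else 0.0
        for well_i in range(1, spec.wells_per_day + 1):
            well_eff = (
                rng.normal(0.0, spec.between_well_sd_um) if spec.between_well_sd_um else 0.0
            )
            noise = (
                rng.normal(0.0, spec.within_well_sd_um, size=spec.droplets_per_well)
                if spec.within_well_sd_um
                else np.zeros(spec.droplets_per_well)
            )
            d = spec.mean_diameter_um + day_eff + well_eff + noise
            well = f"D{day}W{well_i}"
            for val in d:
                rows.append((droplet_id, well, f"C{day}", day, float(val)))
                droplet_id += 1
    return pd.DataFrame(
        rows, columns=["droplet_id", "well", "cartridge", "day", "diameter_um"]
    )


@dataclass
class PartitionCountSpec:
    """Inverse model of the Poisson estimator: known concentration in,
    binomial positive-partition counts out.

    ``concentration`` is copies/uL of the *undiluted* sample; the mean copies
    per partition is m = (concentration / dilution) * Vd(uL), and positives
    are Binomial(R, 1 - e^-m).
    """

    concentration: float = 115_351.0
    dilution: float = 100.0
    vd_nl: float = 0.85
    accepted_partitions: int = 15_000
    replicates: int = 18
    target: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vd_nl <= 0:
            raise ValueError("partition volume must be positive")
        if self.accepted_partitions < 1:
            raise ValueError("need >= 1 accepted partition")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def mean_copies_per_partition(self) -> float:
        return (self.concentration / self.dilution) * (self.vd_nl * 1e-3)

    @property
    def positive_probability(self) -> float:
        return float(-np.expm1(-self.mean_copies_per_partition))


def generate_partition_counts(spec: PartitionCountSpec) -> list[ReactionResult]:
    """Draw per-reaction positive-partition counts for the spec's conditions.

    Warns when the positive probability rounds to 1 in double precision
    (saturation: the concentration estimator is undefined at P = R, so such
    draws are unusable downstream).
    """
    p = spec.positive_probability
    if p >= 1.0:
        warnings.warn(
            "positive probability rounds to 1 (saturation); estimator undefined at P=R",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    draws = rng.binomial(spec.accepted_partitions, p, size=spec.replicates)
    return [
        ReactionResult(
            well=f"W{i + 1:02d}",
            target=spec.target,
            positives=int(P),
            accepted=spec.accepted_partitions,
            vd_nl=spec.vd_nl,
            dilution=spec.dilution,
        )
        for i, P in enumerate(draws)
    ]


def generate_duplex_wells(
    concentrations: dict[str, dict[str, float]],
    days: int = 3,
    replicates_per_day: int = 6,
    ntc_per_day: int = 2,
    accepted_partitions: int = 15_000,
    vd_nl: float = 0.85,
    dilution: float = 100.0,
    seed: int = 0,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Synthesize a duplex two-generator wells table (QuantaSoft-export-like).

    ``concentrations`` maps generator -> {target: true copies/uL of the
    undiluted sample}; each generator gets ``days x replicates_per_day``
    sample wells plus ``ntc_per_day`` negative template controls per day,
    both targets sharing each well's accepted-partition count.  With
    ``deterministic=True`` positives are the rounded expectation
    ``round(R * (1 - e^-m))`` instead of binomial draws, which pins the
    per-generator mean concentrations at the requested values to ~0.01%.

    Returns a DataFrame with columns well, day, generator, target,
    positives, accepted, dilution, is_ntc.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gen, targets in concentrations.items():
        for day in range(1, days + 1):
            for rep in range(1, replicates_per_day + 1):
                well = f"{gen}-D{day}R{rep}"
                for target, conc in targets.items():
                    m = (conc / dilution) * (vd_nl * 1e-3)
                    p = float(-np.expm1(-m))
                    if deterministic:
                        positives = int(round(accepted_partitions * p))
                    else:
                        positives = int(rng.binomial(accepted_partitions, p))
                    rows.append((well, day, gen, target, positives, accepted_partitions, dilution, False))
            for ntc_i in range(1, ntc_per_day + 1):
                well = f"{gen}-D{day}NTC{ntc_i}"
                for target in targets:
                    positives = 0 if deterministic else int(rng.poisson(0.2))
                    rows.append((well, day, gen, target, positives, accepted_partitions, dilution, True))
    return pd.DataFrame(
        rows,
        columns=["well", "day", "generator", "target", "positives", "accepted", "dilution", "is_ntc"],
    )
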