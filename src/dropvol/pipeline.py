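"""End-to-end orchestration: diameters -> volumes -> budget -> quantification.

Two entry points mirror the two halves of the analysis:

``run_volume_study``
    From a droplet-diameter table (measured from micrographs or synthetic):
    per-well summaries, a Grubbs screen on well mean volumes, per-day and
    overall mean diameter/volume, a one-way ANOVA across days, Tukey
    pairwise comparisons, and the bottom-up uncertainty budget with its
    expanded uncertainty U = k u_c.

``run_quantification``
    From a wells table of partition counts: QC filtering, concentrations at
    a fixed droplet volume and at per-generator measured volumes,
    inter-generator bias, GM% (volume-free), RSDr and RSD_R.

Reports are plain dataclasses with ``to_frame`` methods so drivers can write
CSV/JSON; re-running with the same inputs and config is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import quant, volume_stats
from .imaging import SegmentationParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "VolumeStudyReport", "QuantReport", "run_volume_study", "run_quantification"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run, recorded in every report."""

    pixel_size_um: float = 0.5
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05  # Grubbs / ANOVA / Tukey significance level
    k: float = 2.1  # coverage factor for expanded uncertainty
    #: "droplet": ANOVA on per-droplet volumes grouped by day (all
    #: measurements taken into account; n = droplets per day).
    #: "well_means": ANOVA on per-well mean volumes grouped by day
    #: (n = wells per day).
    budget_level: str = "droplet"
    fixed_vd_nl: float = 0.85
    measured_vd_nl: Mapping[str, float] | None = None  # generator -> nL
    #: bias denominator; None = alphabetically first generator (e.g. DG32
    #: before DG8, matching the convention that the automated generator is
    #: the reference)
    reference_generator: str | None = None
    ntc_positive_threshold: int = 5
    seed: int = 0


@dataclass
class VolumeStudyReport:
    well_summaries: list
    outlier_screen: volume_stats.OutlierScreenResult
    excluded_wells: list
    per_day: pd.DataFrame
    overall_mean_diameter_um: float
    overall_sd_diameter_um: float
    overall_mean_volume_nl: float
    overall_sd_volume_nl: float
    inter_well_rsd_percent: float
    anova: volume_stats.AnovaResult
    tukey: pd.DataFrame
    budget: volume_stats.UncertaintyBudget
    config: RunConfig

    def to_frame(self) -> pd.DataFrame:
        """Per-day volume summary: one row per day plus an overall row."""
        rows = self.per_day.copy()
        overall = pd.DataFrame(
            [
                {
                    "day": "mean",
                    "n_droplets": int(rows["n_droplets"].sum()),
                    "mean_diameter_um": self.overall_mean_diameter_um,
                    "sd_diameter_um": self.overall_sd_diameter_um,
                    "mean_volume_nl": self.overall_mean_volume_nl,
                    "sd_volume_nl": self.overall_sd_volume_nl,
                    "expanded_uncertainty_nl": self.budget.U,
                }
            ]
        )
        return pd.concat([rows, overall], ignore_index=True)


def run_volume_study(diameters: pd.DataFrame, config: RunConfig | None = None) -> VolumeStudyReport:
    """Volume metrology on a droplet table with columns
    ``well, day, diameter_um`` (``cartridge`` optional).

    Grubbs screening operates on per-well mean volumes; flagged wells are
    excluded from all downstream statistics.  The uncertainty budget groups
    by day (N = days) with n = replicates per day at the configured level.
    """
    if config is None:
        config = RunConfig()
    required = {"well", "day", "diameter_um"}
    missing = required - set(diameters.columns)
    if missing:
        raise ValueError(f"diameter table missing columns: {sorted(missing)}")
    if diameters.empty:
        raise ValueError("diameter table is empty")
    days = sorted(diameters["day"].unique())
    if len(days) < 2:
        raise ValueError(
            f"uncertainty budget needs measurements from >= 2 days, got {len(days)}"
        )

    df = diameters.copy()
    df["volume_nl"] = volume_stats.droplet_volume(df["diameter_um"].to_numpy())

    # per-well summaries and Grubbs screen on well mean volumes
    summaries = []
    for (well, day), sub in df.groupby(["well", "day"], sort=True):
        cart = str(sub["cartridge"].iloc[0]) if "cartridge" in sub else ""
        summaries.append(
            volume_stats.summarize_well(
                sub["diameter_um"].to_numpy(), well=str(well), cartridge=cart, day=int(day)
            )
        )
    well_means = np.array([s.mean_volume_nl for s in summaries])
    well_labels = [s.well for s in summaries]
    screen = volume_stats.grubbs_screen(well_means, alpha=config.alpha, labels=well_labels)
    excluded = screen.outlier_labels
    if excluded:
        logger.info("Grubbs screen excluded wells: %s", excluded)
    kept = df[~df["well"].isin(excluded)]

    per_day_rows = []
    for day, sub in kept.groupby("day", sort=True):
        per_day_rows.append(
            {
                "day": day,
                "n_droplets": int(len(sub)),
                "mean_diameter_um": float(sub["diameter_um"].mean()),
                "sd_diameter_um": float(sub["diameter_um"].std(ddof=1)),
                "mean_volume_nl": float(sub["volume_nl"].mean()),
                "sd_volume_nl": float(sub["volume_nl"].std(ddof=1)),
            }
        )
    per_day = pd.DataFrame(per_day_rows)

    if config.budget_level == "droplet":
        groups = {int(day): sub["volume_nl"].to_numpy() for day, sub in kept.groupby("day")}
    elif config.budget_level == "well_means":
        kept_sum = [s for s in summaries if s.well not in excluded]
        groups = {}
        for s in kept_sum:
            groups.setdefault(s.day, []).append(s.mean_volume_nl)
        groups = {d: np.asarray(v) for d, v in groups.items()}
    else:
        raise ValueError(f"unknown budget_level {config.budget_level!r}")

    anova = volume_stats.anova_oneway(groups)
    tukey = volume_stats.tukey_pairwise(groups, alpha=config.alpha)
    budget = volume_stats.uncertainty_budget(groups, k=config.k)

    kept_means = well_means[screen.kept_mask]
    return VolumeStudyReport(
        well_summaries=summaries,
        outlier_screen=screen,
        excluded_wells=excluded,
        per_day=per_day,
        overall_mean_diameter_um=float(kept["diameter_um"].mean()),
        overall_sd_diameter_um=float(kept["diameter_um"].std(ddof=1)),
        overall_mean_volume_nl=float(kept["volume_nl"].mean()),
        overall_sd_volume_nl=float(kept["volume_nl"].std(ddof=1)),
        inter_well_rsd_percent=volume_stats.relative_sd(kept_means),
        anova=anova,
        tukey=tukey,
        budget=budget,
        config=config,
    )


@dataclass
class QuantReport:
    comparison: quant.ComparisonReport
    qc_log: list
    ntc_table: pd.DataFrame
    contamination_warnings: list
    config: RunConfig

    def to_frame(self) -> pd.DataFrame:
        """Copy-number comparison table: volume setting x target x generator."""
        gen_a, gen_b = self.comparison.generators
        rows = []
        for setting, vols in self.comparison.volume_settings.items():
            targets = sorted({t for (s, t, _) in self.comparison.concentrations if s == setting})
            for target in targets:
                rows.append(
                    {
                        "volume_setting": setting,
                        "vd_nl": "/".join(f"{vols[g]:g}" for g in (gen_a, gen_b)),
                        "target": target,
                        f"{gen_a}_copies_per_ul": self.comparison.concentrations[
                            (setting, target, gen_a)
                        ],
                        f"{gen_b}_copies_per_ul": self.comparison.concentrations[
                            (setting, target, gen_b)
                        ],
                        "bias_percent": self.comparison.bias[(setting, target)],
                        "rsd_R_percent": self.comparison.rsd_repro[(setting, target)],
                    }
                )
        return pd.DataFrame(rows)


def run_quantification(wells: pd.DataFrame, config: RunConfig | None = None) -> QuantReport:
    """Absolute quantification and generator comparison from a wells table.

    Expected columns: ``well, target, generator, positives, accepted``;
    optional ``dilution`` (default 1) and ``is_ntc`` (default False).
    Concentrations are computed at ``config.fixed_vd_nl``; when
    ``config.measured_vd_nl`` supplies per-generator volumes the report adds
    the measured-volume setting.  GM% is computed per replicate well from
    the partition counts of the two targets, where the droplet volume
    cancels exactly — so GM% is identical under every volume setting.
    """
    if config is None:
        config = RunConfig()
    required = {"well", "target", "generator", "positives", "accepted"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    df = wells.copy()
    if "dilution" not in df:
        df["dilution"] = 1.0
    if "is_ntc" not in df:
        df["is_ntc"] = False

    reactions = [
        quant.ReactionResult(
            well=str(r.well),
            target=str(r.target),
            positives=int(r.positives),
            accepted=int(r.accepted),
            vd_nl=config.fixed_vd_nl,
            dilution=float(r.dilution),
            is_ntc=bool(r.is_ntc),
        )
        for r in df.itertuples()
    ]
    passed, qc_log = quant.qc_filter(reactions)
    for well, reason in qc_log:
        logger.info("QC rejected %s: %s", well, reason)
    if not any(not r.is_ntc for r in passed):
        raise ValueError("all sample reactions were QC-rejected; nothing to quantify")

    ntcs = [r for r in passed if r.is_ntc]
    samples = [r for r in passed if not r.is_ntc]
    contamination = []
    for r in ntcs:
        if r.positives > config.ntc_positive_threshold:
            msg = (
                f"NTC {r.well}/{r.target}: {r.positives} positive droplets "
                f"(> {config.ntc_positive_threshold}); possible contamination"
            )
            contamination.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    ntc_table = pd.DataFrame(
        {
            "well": [r.well for r in ntcs],
            "target": [r.target for r in ntcs],
            "positives": [r.positives for r in ntcs],
            "accepted": [r.accepted for r in ntcs],
        }
    )

    gens = sorted({r for r in df.loc[~df["is_ntc"], "generator"].astype(str)})
    if len(gens) == 1:
        generators = (gens[0], gens[0])
    elif len(gens) == 2:
        ref = config.reference_generator or gens[0]
        if ref not in gens:
            raise ValueError(f"reference generator {ref!r} not among {gens}")
        test = next(g for g in gens if g != ref)
        generators = (test, ref)  # bias = test vs reference
    else:
        raise ValueError(f"expected 1 or 2 generators, got {gens}")
    gen_of_well = {str(r.well): str(r.generator) for r in df.itertuples()}

    targets = sorted({r.target for r in samples})
    replicate_conc: dict[tuple[str, str], list[float]] = {
        (g, t): [] for g in generators for t in targets
    }
    by_well: dict[str, dict[str, quant.ReactionResult]] = {}
    for r in samples:
        if r.positives == 0:
            # negative sample well: concentration 0; excluded from GM% ratios
            replicate_conc[(gen_of_well[r.well], r.target)].append(0.0)
            continue
        replicate_conc[(gen_of_well[r.well], r.target)].append(r.concentration())
        by_well.setdefault(r.well, {})[r.target] = r

    gm_replicates = None
    gm_target = endo_target = None
    if len(targets) == 2:
        # convention: the endogene is the reference (higher-copy) channel; take
        # the second target alphabetically as GM unless names make it obvious
        gm_target, endo_target = targets[0], targets[1]
        means = {
            t: np.mean(replicate_conc[(generators[0], t)] + replicate_conc[(generators[1], t)])
            for t in targets
        }
        if means[gm_target] > means[endo_target]:
            gm_target, endo_target = endo_target, gm_target
        gm_replicates = {g: [] for g in generators}
        for well, pair in sorted(by_well.items()):
            if gm_target in pair and endo_target in pair:
                g = gen_of_well[well]
                gm_replicates[g].append(
                    quant.gm_percent_from_counts(
                        pair[gm_target].positives,
                        pair[endo_target].positives,
                        pair[endo_target].accepted,
                    )
                )
        if not all(len(v) >= 1 for v in gm_replicates.values()):
            gm_replicates = None

    comparison = quant.build_comparison(
        {k: np.asarray(v) for k, v in replicate_conc.items() if len(v)},
        generators=generators,
        fixed_vd_nl=config.fixed_vd_nl,
        measured_vd_nl=dict(config.measured_vd_nl) if config.measured_vd_nl else None,
        gm_target=gm_target,
        endogene=endo_target,
        gm_replicates=gm_replicates,
        k=config.k,
    )
    return QuantReport(
        comparison=comparison,
        qc_log=qc_log,
        ntc_table=ntc_table,
        contamination_warnings=contamination,
        config=config,
    )
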