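"""Poisson absolute quantification for droplet digital PCR.

In ddPCR a reaction is partitioned into ~nL droplets and, after end-point
amplification, each droplet is read as positive or negative.  Under random
partitioning the number of target copies per droplet is Poisson, so the mean
copies per partition is recovered from the fraction of negative droplets:

    Tc = -ln(1 - P/R) * (1 / Vd) * D

where ``P`` is the number of positive partitions, ``R`` the number of
accepted (analysed) partitions, ``Vd`` the single-partition volume and ``D``
the dilution factor of the original sample.  Because the concentration is
linear in ``1/Vd``, any error in the assumed droplet volume propagates
one-to-one into the reported copy number; the functions here make that
rescaling, the resulting inter-instrument bias, and the volume-invariant
GM% (transgene/endogene ratio) explicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MIN_ACCEPTED_PARTITIONS",
    "ReactionResult",
    "CopyNumberEstimate",
    "ComparisonReport",
    "SaturationError",
    "concentration_from_counts",
    "rescale_concentration",
    "qc_filter",
    "bias_percent",
    "volume_induced_bias",
    "gm_percent",
    "gm_percent_from_counts",
    "rsd_repeatability",
    "rsd_reproducibility",
    "build_comparison",
]

#: QC rejection threshold: reactions with fewer accepted partitions than this
#: (per 20 uL PCR) are excluded from analysis.  The rule is strict: exactly
#: 10,000 accepted partitions passes.
MIN_ACCEPTED_PARTITIONS = 10_000

#: GMO-testing minimum performance limits for repeatability / reproducibility
#: relative standard deviations, in percent.
RSDR_LIMIT = 25.0
RSDR_REPRO_LIMIT = 35.0


class SaturationError(ValueError):
    """All partitions positive: the Poisson estimator is undefined at P = R."""


@dataclass
class ReactionResult:
    """One ddPCR reaction (well x target) as exported by the droplet reader.

    Attributes
    ----------
    well, target:
        Identifiers; a duplex assay yields two records per well.
    positives, accepted:
        Positive partition count P and accepted partition count R.
    vd_nl:
        Partition (droplet) volume in nL used for quantification.
    dilution:
        Dilution factor D of the original sample in the PCR (>= 1).
    is_ntc:
        Negative template control flag; NTCs are reported separately and are
        never included in concentration means.
    qc_status:
        "unchecked", "pass" or "fail:<reason>"; set by :func:`qc_filter`.
    """

    well: str
    target: str
    positives: int
    accepted: int
    vd_nl: float = 0.85
    dilution: float = 1.0
    is_ntc: bool = False
    qc_status: str = "unchecked"

    def __post_init__(self) -> None:
        if not 0 <= self.positives <= self.accepted:
            raise ValueError(
                f"need 0 <= positives <= accepted, got P={self.positives}, R={self.accepted}"
            )
        if self.vd_nl <= 0:
            raise ValueError(f"partition volume must be positive, got {self.vd_nl}")
        if self.dilution < 1:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution}")

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.accepted

    def concentration(self, vd_nl: float | None = None) -> float:
        """Concentration in copies/uL of the undiluted sample (Poisson estimate)."""
        vd = self.vd_nl if vd_nl is None else vd_nl
        return concentration_from_counts(self.positives, self.accepted, vd, self.dilution)


@dataclass
class CopyNumberEstimate:
    """A concentration estimate with the volume that produced it."""

    concentration: float  # copies/uL
    vd_nl: float
    replicate_set: str = ""
    expanded_uncertainty: float | None = None


def concentration_from_counts(
    positives: int, accepted: int, vd_nl: float, dilution: float = 1.0
) -> float:
    """Poisson concentration estimate, copies/uL of the undiluted sample.

    ``-ln(1 - P/R)`` is the mean copies per partition; dividing by the
    partition volume (nL converted to uL) and multiplying by the dilution
    factor gives the sample concentration.

    Raises
    ------
    SaturationError
        If every partition is positive (P = R), where the estimator diverges.
    ValueError
        For P > R, P < 0 or a non-positive volume.
    """
    if vd_nl <= 0:
        raise ValueError(f"partition volume must be positive, got {vd_nl} nL")
    if positives < 0 or positives > accepted:
        raise ValueError(f"need 0 <= P <= R, got P={positives}, R={accepted}")
    if positives == accepted:
        raise SaturationError(
            f"all {accepted} partitions positive; concentration is unbounded"
        )
    lam = -math.log1p(-positives / accepted)  # mean copies per partition
    return lam / (vd_nl * 1e-3) * dilution


def rescale_concentration(tc: float, vd_old_nl: float, vd_new_nl: float) -> float:
    """Re-express a concentration computed with one partition volume under another.

    Follows from the linearity of the Poisson estimator in 1/Vd:
    ``Tc_new = Tc_old * Vd_old / Vd_new``.  ``Tc * Vd`` is invariant.
    """
    if vd_old_nl <= 0 or vd_new_nl <= 0:
        raise ValueError("partition volumes must be positive")
    if tc < 0:
        raise ValueError(f"concentration must be non-negative, got {tc}")
    return tc * vd_old_nl / vd_new_nl


def qc_filter(
    reactions: Iterable[ReactionResult],
) -> tuple[list[ReactionResult], list[tuple[str, str]]]:
    """Partition-count QC: reject reactions with R < 10,000 accepted partitions.

    Returns the accepted reactions (qc_status set to "pass") and a rejection
    log of ``(well, reason)`` pairs.  The boundary R = 10,000 is accepted
    (the rule is a strict inequality).
    """
    accepted: list[ReactionResult] = []
    log: list[tuple[str, str]] = []
    for rxn in reactions:
        if rxn.accepted < MIN_ACCEPTED_PARTITIONS:
            rxn.qc_status = "fail:low-partition-count"
            log.append(
                (rxn.well, f"accepted partitions {rxn.accepted} < {MIN_ACCEPTED_PARTITIONS}")
            )
        else:
            rxn.qc_status = "pass"
            accepted.append(rxn)
    return accepted, log


def bias_percent(value: float, reference: float) -> float:
    """Relative bias of ``value`` against ``reference``, in percent.

    For inter-generator comparisons the DG32 result is the reference
    (denominator).
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


def volume_induced_bias(v_fixed_nl: float, v_measured_nl: float) -> float:
    """Copy-number understatement (%) caused by using a too-large fixed volume.

    Equals ``100 * (V_fixed - V_measured) / V_fixed``: the relative amount by
    which concentrations computed at the fixed volume fall short of the
    volume-corrected ones.
    """
    if v_fixed_nl <= 0 or v_measured_nl <= 0:
        raise ValueError("volumes must be positive")
    return 100.0 * (v_fixed_nl - v_measured_nl) / v_fixed_nl


def gm_percent(gm_target: float, endogene: float) -> float:
    """GM content as percent: 100 x (GM-event copies) / (endogene copies)."""
    if endogene <= 0:
        raise ValueError("endogene concentration must be positive")
    if gm_target < 0:
        raise ValueError("GM-target concentration must be non-negative")
    return 100.0 * gm_target / endogene


def gm_percent_from_counts(
    positives_gm: int, positives_endo: int, accepted: int
) -> float:
    """GM% computed directly from partition counts of a duplex reaction.

    The partition volume and dilution factor cancel exactly in the
    target/endogene concentration ratio, so GM% is computed volume-free:
    ``100 * ln(1 - P_gm/R) / ln(1 - P_endo/R)``.  This makes GM% identical —
    bit for bit — whether a fixed or a measured droplet volume is assumed.
    """
    if positives_endo == 0:
        raise ValueError("endogene has zero positives; GM% undefined")
    if positives_gm == accepted or positives_endo == accepted:
        raise SaturationError("saturated channel; GM% undefined")
    num = -math.log1p(-positives_gm / accepted)
    den = -math.log1p(-positives_endo / accepted)
    return 100.0 * num / den


def _rsd(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return 100.0 * values.std(ddof=1) / mean


def rsd_repeatability(replicates: Sequence[float]) -> float:
    """Relative repeatability SD (%): sample SD / mean within one instrument."""
    return _rsd(np.asarray(replicates))


def rsd_reproducibility(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Relative reproducibility SD (%): RSD over the pooled values of two
    instrument groups (same method, same items, different equipment)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    return _rsd(np.concatenate([a, b]))


@dataclass
class ComparisonReport:
    """Two-generator comparison at a fixed and a measured volume setting.

    ``concentrations`` maps (volume_setting, target, generator) to the mean
    concentration in copies/uL; ``bias`` maps (volume_setting, target) to the
    percent bias of the first generator against the second (reference).
    GM% is volume-free and therefore carries no volume_setting key.
    """

    generators: tuple[str, str]
    volume_settings: Mapping[str, Mapping[str, float]]  # setting -> generator -> Vd (nL)
    concentrations: dict = field(default_factory=dict)
    bias: dict = field(default_factory=dict)
    gm_percent: dict = field(default_factory=dict)  # generator -> mean GM%
    gm_percent_u: dict = field(default_factory=dict)  # generator -> expanded U of GM%
    gm_bias: float | None = None
    rsd_r: dict = field(default_factory=dict)  # (generator, target) -> RSDr %
    rsd_repro: dict = field(default_factory=dict)  # (setting, target) -> RSD_R %
    performance_flags: dict = field(default_factory=dict)

    def within_performance_limits(self) -> bool:
        return all(self.performance_flags.values())


def build_comparison(
    replicate_concentrations: Mapping[tuple[str, str], Sequence[float]],
    generators: tuple[str, str],
    fixed_vd_nl: float,
    measured_vd_nl: Mapping[str, float] | None = None,
    gm_target: str | None = None,
    endogene: str | None = None,
    gm_replicates: Mapping[str, Sequence[float]] | None = None,
    k: float = 2.1,
) -> ComparisonReport:
    """Assemble a two-generator comparison report.

    Parameters
    ----------
    replicate_concentrations:
        (generator, target) -> per-replicate concentrations at the *fixed*
        volume, copies/uL.
    generators:
        (test, reference) pair; bias is test vs reference.
    measured_vd_nl:
        Per-generator measured droplet volumes.  When omitted, only the
        fixed-volume setting is reported.
    gm_replicates:
        generator -> per-replicate GM% values (computed volume-free upstream);
        when given together with ``gm_target``/``endogene`` names, the report
        carries mean GM% +- k*s/sqrt(n).
    """
    gen_a, gen_b = generators
    settings: dict[str, dict[str, float]] = {
        "fixed": {gen_a: fixed_vd_nl, gen_b: fixed_vd_nl}
    }
    if measured_vd_nl is not None:
        settings["measured"] = dict(measured_vd_nl)
    report = ComparisonReport(generators=generators, volume_settings=settings)

    targets = sorted({t for (_, t) in replicate_concentrations})
    for setting, vols in settings.items():
        for target in targets:
            means = {}
            for gen in generators:
                reps = np.asarray(replicate_concentrations[(gen, target)], dtype=float)
                scaled = reps * (fixed_vd_nl / vols[gen])
                means[gen] = float(scaled.mean())
                report.concentrations[(setting, target, gen)] = means[gen]
            report.bias[(setting, target)] = (
                bias_percent(means[gen_a], means[gen_b])
                if means[gen_b] != 0
                else float("nan")
            )
            pooled_a = np.asarray(replicate_concentrations[(gen_a, target)]) * (
                fixed_vd_nl / vols[gen_a]
            )
            pooled_b = np.asarray(replicate_concentrations[(gen_b, target)]) * (
                fixed_vd_nl / vols[gen_b]
            )
            try:
                rsdR = rsd_reproducibility(pooled_a, pooled_b)
            except ValueError:  # zero mean (e.g. an all-negative target)
                rsdR = float("nan")
            report.rsd_repro[(setting, target)] = rsdR
            report.performance_flags[f"rsd_R:{setting}:{target}"] = (
                not np.isfinite(rsdR) or rsdR <= RSDR_REPRO_LIMIT
            )

    for (gen, target), reps in replicate_concentrations.items():
        try:
            rsdr = rsd_repeatability(reps)
        except ValueError:
            rsdr = float("nan")
        report.rsd_r[(gen, target)] = rsdr
        report.performance_flags[f"rsd_r:{gen}:{target}"] = (
            not np.isfinite(rsdr) or rsdr <= RSDR_LIMIT
        )

    if gm_replicates is not None:
        for gen in generators:
            reps = np.asarray(gm_replicates[gen], dtype=float)
            report.gm_percent[gen] = float(reps.mean())
            if reps.size >= 2:
                report.gm_percent_u[gen] = float(k * reps.std(ddof=1) / np.sqrt(reps.size))
        report.gm_bias = bias_percent(report.gm_percent[gen_a], report.gm_percent[gen_b])
    return report
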