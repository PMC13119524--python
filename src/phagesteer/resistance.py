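"""Resistance coefficients from liquid killing assays.

The resistance coefficient (RC) compares an isolate's log survival ratio
under a 30-min phage challenge to a same-day wild-type benchmark:

    RC = [ln(WT_P/WT_NP) - ln(Iso_P/Iso_NP)] / ln(WT_P/WT_NP)

Because short-interval growth and killing are both exponential
(dN/dt = rN - phi*P*N), the log ratio ln(N_P/N_NP) isolates the per-capita
killing term and cancels the isolate's intrinsic growth rate; dividing by the
wild-type log ratio makes the statistic dimensionless and robust to day
effects and titer variation.  RC = 0 means wild-type-like susceptibility,
RC = 1 an unkilled (fully resistant) isolate, RC < 0 hypersensitivity.

Two-phage profiles are classified into the quadrants of an RC(T2) x
RC(lambda) plane: cross-resistance (both positive), collateral sensitivity
(opposite signs, both significant), single-phage resistance (one positive,
the other indistinguishable from 0), double sensitivity (both negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KillingAssayRecord",
    "RCEstimate",
    "ResistanceProfile",
    "Quadrant",
    "InvalidRecordError",
    "InvalidBenchmarkError",
    "compute_rc",
    "rc_confidence_interval",
    "classify_profile",
    "rc_invariance_check",
]


class InvalidRecordError(ValueError):
    """A killing-assay record has non-positive densities."""


class InvalidBenchmarkError(ValueError):
    """The wild-type benchmark is invalid (phage failed to kill WT)."""


@dataclass(frozen=True)
class KillingAssayRecord:
    """The four CFU/mL densities entering the RC formula.

    ``iso_p``/``iso_np``: isolate density after 30 min with / without phage.
    ``wt_p``/``wt_np``: the paired wild-type benchmark from the same day.
    ``below_detection``: the phage-exposed isolate count fell below the
    plating detection limit and was imputed at the limit (RC is then a lower
    bound on sensitivity).
    """

    isolate_id: str
    day: int
    phage: str
    iso_p: float
    iso_np: float
    wt_p: float
    wt_np: float
    replicate_index: int = 1
    below_detection: bool = False


@dataclass(frozen=True)
class RCEstimate:
    """Mean RC over replicate assays with a 95% confidence interval."""

    phage: str
    rc: float
    ci_low: float
    ci_high: float
    n_replicates: int
    significant: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicates > 1 and not (
            math.isnan(self.ci_low)
            or self.ci_low - 1e-12 <= self.rc <= self.ci_high + 1e-12
        ):
            raise ValueError("confidence interval must bracket the point estimate")


class Quadrant(str, Enum):
    CROSS_RESISTANT = "cross_resistant"
    T2_ONLY_RESISTANT = "t2_only_resistant"
    LAMBDA_ONLY_RESISTANT = "lambda_only_resistant"
    COLLATERAL_SENSITIVE_T2RES = "collateral_sensitive_t2res"
    COLLATERAL_SENSITIVE_LAMBDARES = "collateral_sensitive_lambdares"
    DOUBLE_SENSITIVE = "double_sensitive"
    WT_LIKE = "wt_like"


@dataclass(frozen=True)
class ResistanceProfile:
    """Two-phage resistance profile of one isolate."""

    isolate_id: str
    day: int
    rc_t2: RCEstimate
    rc_lambda: RCEstimate
    quadrant: Quadrant
    significant: bool


def _validate(record: KillingAssayRecord) -> None:
    for name in ("iso_p", "iso_np", "wt_p", "wt_np"):
        value = getattr(record, name)
        if not (value > 0) or not math.isfinite(value):
            raise InvalidRecordError(
                f"{record.isolate_id}/{record.phage} rep {record.replicate_index}: "
                f"{name} = {value!r} must be a positive finite density"
            )
    if record.wt_p >= record.wt_np:
        raise InvalidBenchmarkError(
            f"{record.isolate_id}/{record.phage} rep {record.replicate_index}: "
            f"wt_p >= wt_np ({record.wt_p:g} >= {record.wt_np:g}); "
            "phage failed to kill the wild type that day"
        )


def compute_rc(record: KillingAssayRecord) -> float:
    """Resistance coefficient of a single killing-assay record."""
    _validate(record)
    wt_lr = math.log(record.wt_p / record.wt_np)
    iso_lr = math.log(record.iso_p / record.iso_np)
    return (wt_lr - iso_lr) / wt_lr


def rc_confidence_interval(
    records: Sequence[KillingAssayRecord],
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "bootstrap",
) -> RCEstimate:
    """Mean RC over replicate records with a 95% CI.

    The default CI is a nonparametric percentile bootstrap over replicate
    assay records (no distributional assumption on log-ratio noise);
    ``method="normal"`` gives the closed-form t interval instead.  A single
    replicate yields a flagged point estimate with an undefined CI.
    ``significant`` means the CI excludes 0.
    """
    records = list(records)
    if not records:
        raise InvalidRecordError("no killing-assay records supplied")
    phages = {r.phage for r in records}
    if len(phages) != 1:
        raise ValueError(f"records mix phages: {sorted(phages)}")
    (phage,) = phages

    values, flags, reasons = [], [], []
    for record in records:
        try:
            values.append(compute_rc(record))
        except (InvalidRecordError, InvalidBenchmarkError) as exc:
            reasons.append(str(exc))
            continue
        if record.below_detection:
            flags.append("below_detection")
    if not values:
        raise InvalidRecordError(
            "all records invalid:\n" + "\n".join(f"- {r}" for r in reasons)
        )
    if reasons:
        flags.append("dropped_invalid")
    values_arr = np.asarray(values, dtype=float)
    mean = float(values_arr.mean())
    n = len(values_arr)

    if n == 1:
        return RCEstimate(
            phage, mean, math.nan, math.nan, 1, False,
            tuple(sorted(set(flags)) + ["point_estimate"]),
        )

    if method == "bootstrap":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = values_arr[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
    elif method == "normal":
        from scipy import stats as sps

        se = values_arr.std(ddof=1) / math.sqrt(n)
        t = sps.t.ppf(0.975, n - 1)
        lo, hi = mean - t * se, mean + t * se
    else:
        raise ValueError(f"unknown CI method {method!r}")

    lo = min(float(lo), mean)
    hi = max(float(hi), mean)
    significant = not (lo <= 0.0 <= hi)
    return RCEstimate(phage, mean, lo, hi, n, significant, tuple(sorted(set(flags))))


def classify_profile(rc_t2: RCEstimate, rc_lambda: RCEstimate) -> tuple[Quadrant, bool]:
    """Assign the two-phage quadrant label and an overall significance flag.

    Significance comes first: if neither RC dimension is significant the
    profile is wild-type-like.  Otherwise the signs of the two RC means choose
    the quadrant; with mixed signs, the negative dimension must itself be
    significant to count as collateral sensitivity — otherwise the profile is
    single-phage resistance.
    """
    significant = rc_t2.significant or rc_lambda.significant
    if not significant:
        return Quadrant.WT_LIKE, False
    t2, lam = rc_t2.rc, rc_lambda.rc
    if t2 > 0 and lam > 0:
        return Quadrant.CROSS_RESISTANT, True
    if t2 <= 0 and lam <= 0:
        return Quadrant.DOUBLE_SENSITIVE, True
    if t2 > 0:  # lam <= 0
        if rc_lambda.significant:
            return Quadrant.COLLATERAL_SENSITIVE_T2RES, True
        return Quadrant.T2_ONLY_RESISTANT, True
    if rc_t2.significant:
        return Quadrant.COLLATERAL_SENSITIVE_LAMBDARES, True
    return Quadrant.LAMBDA_ONLY_RESISTANT, True


def rc_invariance_check(record: KillingAssayRecord, scale_factor: float) -> bool:
    """True iff RC is unchanged (within 1e-12) when the isolate densities are
    rescaled by a common factor — the dilution-invariance sanity check."""
    if not (scale_factor > 0) or not math.isfinite(scale_factor):
        raise ValueError("scale_factor must be a positive finite number")
    base = compute_rc(record)
    scaled = KillingAssayRecord(
        record.isolate_id,
        record.day,
        record.phage,
        record.iso_p * scale_factor,
        record.iso_np * scale_factor,
        record.wt_p,
        record.wt_np,
        record.replicate_index,
    )
    return abs(compute_rc(scaled) - base) < 1e-12


def build_profile(
    isolate_id: str,
    day: int,
    t2_records: Iterable[KillingAssayRecord],
    lambda_records: Iterable[KillingAssayRecord],
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ResistanceProfile:
    """Convenience: estimate both RC dimensions and classify the profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rc_t2 = rc_confidence_interval(list(t2_records), n_boot=n_boot, seed=rng)
    rc_lambda = rc_confidence_interval(list(lambda_records), n_boot=n_boot, seed=rng)
    quadrant, significant = classify_profile(rc_t2, rc_lambda)
    return ResistanceProfile(isolate_id, day, rc_t2, rc_lambda, quadrant, significant)
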