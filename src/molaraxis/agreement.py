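"""Agreement statistics for paired angle measurements.

Clinical validation of an automated angle measurement against a human
reference uses three complementary views:

* **error-interval accuracy** — the fraction of teeth whose measurement
  falls within +/-1, +/-2.5 and +/-5 degrees of the reference;
* **Bland-Altman** — bias (mean of test - reference differences) and the
  95% limits of agreement, bias +/- 1.96 x SD of the differences;
* **ICC** — intraclass correlation (two-way random effects, absolute
  agreement, single measurement) with its 95% F-based confidence interval,
  for inter-/intra-observer reliability tables.

Differences are always oriented test - reference, so a negative bias means
the automated method underestimates relative to the manual reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, SampleSizeError

__all__ = [
    "PairedAngles",
    "BlandAltmanResult",
    "IccResult",
    "accuracy_within",
    "bland_altman",
    "icc_absolute_agreement",
    "refinement_summary",
]


@dataclass(frozen=True)
class PairedAngles:
    """Paired reference (manual) and test (automated) angles in degrees."""

    reference: np.ndarray
    test: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise SampleSizeError(
                f"reference/test must be parallel 1D arrays, got shapes "
                f"{ref.shape} and {tst.shape}"
            )
        if len(ref) < 2:
            raise SampleSizeError("paired angles need n >= 2")
        if not (np.isfinite(ref).all() and np.isfinite(tst).all()):
            raise SampleSizeError("paired angles must be finite")
        if self.ids and len(self.ids) != len(ref):
            raise SampleSizeError("ids must parallel the angle lists")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)

    @property
    def differences(self) -> np.ndarray:
        """test - reference, degrees."""
        return self.test - self.reference


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    frac_within_loa: float
    n: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str


def accuracy_within(
    pairs: PairedAngles, half_widths: Sequence[float]
) -> dict[float, float]:
    """Fraction of pairs with |test - reference| <= delta, per half-width.

    The bound is inclusive; half-widths of (1, 2.5, 5) reproduce the
    standard clinical error-interval table.
    """
    if any(hw <= 0 for hw in half_widths):
        raise ValueError("half-widths must be > 0")
    abs_diff = np.abs(pairs.differences)
    return {
        float(hw): float(np.mean(abs_diff <= hw)) for hw in half_widths
    }


def bland_altman(
    pairs: PairedAngles, plot_path: str | None = None
) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement.

    bias = mean(test - reference); sd uses the n-1 (sample) denominator;
    LOA = bias +/- 1.96 sd. ``frac_within_loa`` counts differences inside
    the limits, bounds inclusive. When ``plot_path`` is given, the standard
    difference-vs-mean plot with bias and LOA lines is saved there.
    """
    diffs = pairs.differences
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diffs >= loa_low) & (diffs <= loa_high)))
    if plot_path is not None:
        _plot_bland_altman(pairs, bias, loa_low, loa_high, plot_path)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        frac_within_loa=within,
        n=len(diffs),
    )


def _plot_bland_altman(pairs, bias, loa_low, loa_high, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (pairs.reference + pairs.test) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, pairs.differences, s=12, alpha=0.6)
    ax.axhline(bias, color="k", label=f"bias {bias:.2f}°")
    for y in (loa_low, loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of methods (°)")
    ax.set_ylabel("test − reference (°)")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def icc_absolute_agreement(ratings: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Parameters
    ----------
    ratings
        subjects x raters table of angle measurements; must be complete
        with >= 5 subjects and >= 2 raters.

    The 95% confidence interval uses the standard F-distribution
    formulation for this model.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise MissingDataError("ratings must be a 2D subjects x raters table")
    n_subjects, n_raters = table.shape
    if n_subjects < 5 or n_raters < 2:
        raise MissingDataError(
            f"ICC needs >= 5 subjects and >= 2 raters, got {table.shape}"
        )
    if not np.isfinite(table).all():
        raise MissingDataError("ratings table contains missing values")

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subjects),
            "score": table.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # the absolute-agreement single-rater row is labelled ICC2 or ICC(A,1)
    # depending on the pingouin version
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res.loc[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    icc = float(row["ICC"])
    # degenerate tables (zero within-subject variance) yield an undefined F
    # and NaN bounds; guard those and backend interval rounding
    ci_low = min(ci_low, icc) if np.isfinite(ci_low) else icc
    ci_high = max(ci_high, icc) if np.isfinite(ci_high) else icc
    return IccResult(
        icc=icc,
        ci_low=ci_low,
        ci_high=ci_high,
        model="two-way random, absolute agreement, single measurement (ICC2)",
    )


def refinement_summary(
    original: Sequence[float],
    refined: Sequence[float],
    labels: Sequence[str],
    large_edit_thresholds: tuple[float, float] = (5.0, 10.0),
) -> pd.DataFrame:
    """Descriptive statistics of manual refinements (refined - original).

    Groups the corrections by molar position label and reports mean, SD,
    min, max, n, and the counts of edits exceeding the two magnitude
    thresholds (5 and 10 degrees by default); an ``all`` row aggregates
    over positions.
    """
    orig = np.asarray(original, dtype=float)
    ref = np.asarray(refined, dtype=float)
    if orig.shape != ref.shape or len(orig) != len(labels):
        raise SampleSizeError("original/refined/labels must be parallel lists")
    t1, t2 = large_edit_thresholds
    df = pd.DataFrame({"position": list(labels), "edit": ref - orig})

    def _stats(group: pd.DataFrame) -> pd.Series:
        e = group["edit"]
        return pd.Series(
            {
                "mean": e.mean(),
                "sd": e.std(ddof=1) if len(e) > 1 else 0.0,
                "min": e.min(),
                "max": e.max(),
                "n": len(e),
                f"n_gt_{t1:g}": int((e.abs() > t1).sum()),
                f"n_gt_{t2:g}": int((e.abs() > t2).sum()),
            }
        )

    grouped = df.groupby("position", sort=True).apply(_stats, include_groups=False)
    overall = _stats(df).to_frame().T
    overall.index = ["all"]
    out = pd.concat([grouped, overall])
    for col in ("n", f"n_gt_{t1:g}", f"n_gt_{t2:g}"):
        out[col] = out[col].astype(int)
    return out
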