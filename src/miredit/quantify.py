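"""Relative standard-curve qPCR quantification.

Per-assay standard curves (Cq vs log10 quantity, ordinary least squares) are
inverted to quantities, duplicate wells and dilutions are averaged on the
quantity scale, target quantities are normalized to an endogenous control
assay, and expression is reported relative to the mean of non-transgenic
(NT) baseline samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    assay: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 (100%) at slope -3.3219."""
        return 10 ** (-1.0 / self.slope) - 1.0

    def invert(self, cq: float) -> float:
        return 10 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class RelAbundance:
    sample_id: str
    assay: str
    quantity: float
    normalized: float  # quantity_target / quantity_control
    relative_to_nt: float
    outlier_wells: bool = False


@dataclass
class QuantifyResult:
    abundances: list[RelAbundance]
    errors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": a.sample_id,
                    "assay": a.assay,
                    "quantity": a.quantity,
                    "normalized": a.normalized,
                    "relative_to_nt": a.relative_to_nt,
                    "outlier_wells": a.outlier_wells,
                }
                for a in self.abundances
            ]
        )


def fit_curve(dilutions: list[tuple[float, float]], assay: str = "assay") -> StandardCurve:
    """OLS standard curve from (log10 quantity, Cq) dilution points.

    Requires >= 3 points spanning >= 2 logs; a positive slope indicates a
    failed assay and is reported as a warning, not an error.
    """
    if len(dilutions) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    logq = np.array([d[0] for d in dilutions], dtype=float)
    cq = np.array([d[1] for d in dilutions], dtype=float)
    if logq.max() - logq.min() < 2.0:
        raise ValueError("dilution series must span >= 2 logs")
    res = stats.linregress(logq, cq)
    if res.slope >= 0:
        warnings.warn(f"assay {assay}: positive standard-curve slope")
    return StandardCurve(
        assay=assay,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_curves(series: pd.DataFrame) -> dict[str, StandardCurve]:
    """Per-assay curves from a tidy dilution-series table."""
    out = {}
    for assay, sub in series.groupby("assay"):
        pts = list(zip(sub["log10_quantity"], sub["cq"]))
        out[assay] = fit_curve(pts, assay=assay)
    return out


OUTLIER_DELTA_CQ = 0.5  # duplicate wells further apart are flagged


def _sample_quantity(sub: pd.DataFrame, curve: StandardCurve) -> tuple[float, bool]:
    """Mean quantity over wells/dilutions (quantity scale), outlier flag."""
    quantities = []
    outlier = False
    for _, dsub in sub.groupby("dilution"):
        cqs = dsub["cq"].to_numpy()
        if len(cqs) >= 2 and np.ptp(cqs) > OUTLIER_DELTA_CQ:
            outlier = True
        quantities.extend(curve.invert(c) * d for c, d in zip(cqs, dsub["dilution"]))
    return float(np.mean(quantities)), outlier


def quantify(
    cq_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    control_assay: str,
    nt_samples: set[str],
    target_assays: list[str] | None = None,
) -> QuantifyResult:
    """Relative quantification normalized to a control assay and NT baseline.

    For every sample and target assay: invert the standard curve per well,
    average on the quantity scale, divide by the control-assay quantity of
    the same sample, then divide by the mean normalized value over the NT
    samples.  Samples missing the control assay are skipped with an error
    record; undetected Cq values must simply be absent from the table (never
    encoded as zero).
    """
    result = QuantifyResult(abundances=[])
    assays = target_assays or [
        a for a in cq_table["assay"].unique() if a != control_assay
    ]
    control_q: dict[str, tuple[float, bool]] = {}
    for sample, sub in cq_table[cq_table["assay"] == control_assay].groupby("sample"):
        control_q[sample] = _sample_quantity(sub, curves[control_assay])

    for assay in assays:
        table = cq_table[cq_table["assay"] == assay]
        per_sample: dict[str, tuple[float, bool]] = {}
        for sample, sub in table.groupby("sample"):
            if sample not in control_q:
                result.errors.append(
                    f"{sample}/{assay}: missing control assay Cq; sample skipped"
                )
                continue
            q, out1 = _sample_quantity(sub, curves[assay])
            cq_, out2 = control_q[sample]
            per_sample[sample] = (q / cq_, out1 or out2)

        nt_vals = [v for s, (v, _) in per_sample.items() if s in nt_samples]
        if not nt_vals:
            result.errors.append(f"{assay}: no NT baseline samples; assay skipped")
            continue
        nt_mean = float(np.mean(nt_vals))
        for sample, (norm, outlier) in sorted(per_sample.items()):
            q, _ = _sample_quantity(
                table[table["sample"] == sample], curves[assay]
            )
            result.abundances.append(
                RelAbundance(
                    sample_id=sample,
                    assay=assay,
                    quantity=q,
                    normalized=norm,
                    relative_to_nt=norm / nt_mean,
                    outlier_wells=outlier,
                )
            )
    return result


def correlate(x: list[float], y: list[float]) -> dict[str, float | str]:
    """Pearson and Spearman correlation with a sign summary.

    Zero variance in either vector yields an undefined-correlation flag
    rather than NaN propagation.
    """
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    x_arr, y_arr = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        return {"pearson": float("nan"), "spearman": float("nan"),
                "sign": "undefined (zero variance)"}
    pearson = float(stats.pearsonr(x_arr, y_arr).statistic)
    spearman = float(stats.spearmanr(x_arr, y_arr).statistic)
    if pearson < 0 and spearman < 0:
        sign = "negative"
    elif pearson > 0 and spearman > 0:
        sign = "positive"
    else:
        sign = "mixed"
    return {"pearson": pearson, "spearman": spearman, "sign": sign}
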