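"""Simulated RT-qPCR: Cq tables and standard-curve dilution series.

Cq values follow the log-linear amplification model
``Cq = intercept + slope * log10(quantity)`` with optional Gaussian noise;
a slope of -3.3219 (= -1/log10(2)) corresponds to 100% efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CurveSpec:
    assay: str
    slope: float = -3.3219
    intercept: float = 35.0
    noise_sd: float = 0.0


def simulate_qpcr(
    abundance_truth: dict[str, dict[str, float]],
    curve_specs: list[CurveSpec],
    seed: int = 0,
    dilutions: tuple[int, ...] = (10, 50),
    n_wells: int = 2,
    series_points: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR plate from true per-sample template quantities.

    Parameters
    ----------
    abundance_truth
        ``{sample_id: {assay: quantity}}`` — true relative template amounts,
        all positive.
    curve_specs
        Per-assay slope/intercept (and Cq noise).
    dilutions, n_wells
        Each sample is measured in ``n_wells`` duplicate wells at each
        dilution factor, mirroring common plate layouts.
    series_points
        Ten-fold dilution points of the standard curve per assay (>= 4).

    Returns
    -------
    (cq_table, dilution_series)
        Tidy tables: sample/assay/dilution/well/Cq, and
        assay/log10_quantity/Cq.
    """
    if series_points < 4:
        raise ValueError("dilution series needs >= 4 ten-fold points")
    rng = np.random.default_rng(seed)
    curves = {c.assay: c for c in curve_specs}

    cq_rows = []
    for sample, per_assay in abundance_truth.items():
        for assay, quantity in per_assay.items():
            if quantity <= 0:
                raise ValueError(
                    f"non-positive quantity for {sample}/{assay}: {quantity}"
                )
            spec = curves[assay]
            for dil in dilutions:
                q = quantity / dil
                for well in range(1, n_wells + 1):
                    cq = spec.intercept + spec.slope * np.log10(q)
                    if spec.noise_sd > 0:
                        cq += rng.normal(0.0, spec.noise_sd)
                    cq_rows.append((sample, assay, dil, well, float(cq)))
    cq_table = pd.DataFrame(
        cq_rows, columns=["sample", "assay", "dilution", "well", "cq"]
    )

    series_rows = []
    for spec in curves.values():
        for k in range(series_points):
            logq = -float(k)
            cq = spec.intercept + spec.slope * logq
            if spec.noise_sd > 0:
                cq += rng.normal(0.0, spec.noise_sd)
            series_rows.append((spec.assay, logq, float(cq)))
    series = pd.DataFrame(series_rows, columns=["assay", "log10_quantity", "cq"])
    return cq_table, series
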