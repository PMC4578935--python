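"""Quantitative evaluation of background-corrected fields.

The primary accuracy measure is the masked L1 deviation between the
corrected field and the mean-removed internal reference field,

    L1 = (1 / n_voxels) * sum_{r in m} | b_corr(r) - b_ref(r) |,

with both maps mean-removed inside the mask (the mean field is undetermined
by susceptibility differences, so only the mean-free component is
comparable).  The masked standard deviation of the corrected map serves as a
reference-free proxy that is also available for measured data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from .core import FieldMap, InvalidInputError, Mask
from .chain import ChainConfig, run_chain
from .filters import DipfConfig, dipf, gaussian_background, sphinx_filter
from .simulate import PRESETS, SimulationSample

#: matrix of the full-scale study; Gaussian sigma scales with matrix size
_FULL_MATRIX = PRESETS["paper-full"]
_GF_SIGMA_FULL = 4.0

FilterFunc = Callable[[FieldMap, Mask], FieldMap]


def scaled_gf_sigma(shape: tuple[int, int, int]) -> float:
    """Gaussian sigma in voxels, scaled linearly with matrix size from the
    full-study value of 4 voxels (comparable dimensioning w.r.t. brain size)."""
    ratio = np.mean([s / f for s, f in zip(shape, _FULL_MATRIX)])
    return _GF_SIGMA_FULL * float(ratio)


def _demean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return values - values[mask].mean()


def l1_metric(corrected: FieldMap, reference: FieldMap, mask: Mask) -> float:
    """Masked mean absolute deviation between mean-removed maps, in Hz."""
    mask.require_nonempty()
    if corrected.grid.shape != reference.grid.shape:
        raise InvalidInputError("corrected and reference grids differ")
    m = mask.values
    d = _demean(corrected.values, m) - _demean(reference.values, m)
    return float(np.abs(d[m]).mean())


def masked_sigma(fieldmap: FieldMap, mask: Mask) -> float:
    return float(fieldmap.values[mask.values].std(ddof=0))


# ---------------------------------------------------------------------------
# standard filter set


def make_filter_set(
    gf_sigma: float | None = None,
    sphinx_order: int = 10,
    dipf_config: DipfConfig | None = None,
    chain_config: ChainConfig | None = None,
) -> dict[str, FilterFunc]:
    """The four standard corrections, each returning the corrected field."""
    dipf_config = dipf_config or DipfConfig()
    chain_config = chain_config or ChainConfig(dipf=dipf_config)

    def gf(fieldmap: FieldMap, mask: Mask) -> FieldMap:
        sigma = gf_sigma if gf_sigma is not None else scaled_gf_sigma(fieldmap.grid.shape)
        bg = gaussian_background(fieldmap, mask, sigma)
        return FieldMap(
            fieldmap.grid, np.where(mask.values, fieldmap.values - bg.values, 0.0)
        )

    def sphinx(fieldmap: FieldMap, mask: Mask) -> FieldMap:
        bg, _ = sphinx_filter(fieldmap, mask, sphinx_order)
        return FieldMap(
            fieldmap.grid, np.where(mask.values, fieldmap.values - bg.values, 0.0)
        )

    def dipf_only(fieldmap: FieldMap, mask: Mask) -> FieldMap:
        res = dipf(fieldmap, mask, dipf_config)
        return FieldMap(
            fieldmap.grid,
            np.where(mask.values, fieldmap.values - res.background.values, 0.0),
        )

    def mubafire(fieldmap: FieldMap, mask: Mask) -> FieldMap:
        return run_chain(fieldmap, mask, chain_config).corrected

    return {"GF": gf, "SPHINX": sphinx, "DIPF": dipf_only, "MUBAFIRE": mubafire}


@dataclass
class StudyReport:
    """Per-filter aggregate statistics plus per-sample records."""

    stats: pd.DataFrame      # index: filter; columns: mean_L1, std_L1, mean_sigma, std_sigma, n_samples
    records: pd.DataFrame    # columns: filter, sample, L1, sigma

    def to_csv(self, path) -> None:
        self.stats.to_csv(path)

    def to_json(self) -> str:
        return self.stats.to_json(orient="index")


def run_study(
    samples: list[SimulationSample],
    filter_set: dict[str, FilterFunc] | None = None,
) -> StudyReport:
    """Apply every filter to every sample's observed field; aggregate the L1
    deviation from the reference and the masked sigma of the corrected map."""
    if len(samples) < 1:
        raise InvalidInputError("at least one sample is required")
    filter_set = filter_set or make_filter_set()
    rows = []
    for i, s in enumerate(samples):
        for name, func in filter_set.items():
            corrected = func(s.b_obs, s.mask)
            rows.append(
                {
                    "filter": name,
                    "sample": i,
                    "L1": l1_metric(corrected, s.b_ref, s.mask),
                    "sigma": masked_sigma(corrected, s.mask),
                }
            )
    records = pd.DataFrame(rows)
    g = records.groupby("filter", sort=False)
    stats = pd.DataFrame(
        {
            "mean_L1": g["L1"].mean(),
            "std_L1": g["L1"].std(ddof=0),
            "mean_sigma": g["sigma"].mean(),
            "std_sigma": g["sigma"].std(ddof=0),
            "n_samples": g["L1"].count(),
        }
    )
    return StudyReport(stats=stats, records=records)


def reference_sigma(samples: list[SimulationSample]) -> tuple[float, float]:
    """Mean and std over samples of the reference field's masked sigma."""
    vals = [masked_sigma(s.b_ref, s.mask) for s in samples]
    return float(np.mean(vals)), float(np.std(vals, ddof=0))


def parameter_sweep(
    samples: list[SimulationSample],
    sphinx_orders: list[int] | None = None,
    dipf_iteration_grid: list[int] | None = None,
    include_chain: bool = False,
) -> pd.DataFrame:
    """Normalized error (mean L1 / reference sigma) and wall time per
    parameterization of the standalone filters (and optionally the chain).

    The solid-harmonic basis is built once per sample at the largest order
    and truncated (Gram-Schmidt is sequential), and the conjugate-gradient
    run records snapshots at the requested iteration counts, so the sweep
    costs one run per sample per filter.
    """
    sphinx_orders = sorted(sphinx_orders or [])
    dipf_iteration_grid = sorted(dipf_iteration_grid or [])
    rows = []
    for i, s in enumerate(samples):
        norm = masked_sigma(s.b_ref, s.mask) or 1.0
        m = s.mask.values

        if sphinx_orders:
            t0 = time.perf_counter()
            from . import ssh_basis

            basis = ssh_basis.build_basis(s.mask, max(sphinx_orders))
            for order in sphinx_orders:
                sub = basis.truncated(order)
                _, bg = ssh_basis.project(s.b_obs, sub)
                corr = FieldMap(s.b_obs.grid, np.where(m, s.b_obs.values - bg.values, 0.0))
                rows.append(
                    {
                        "filter": "SPHINX",
                        "param": order,
                        "sample": i,
                        "norm_error": l1_metric(corr, s.b_ref, s.mask) / norm,
                        "wall_time_s": time.perf_counter() - t0,
                    }
                )

        if dipf_iteration_grid:
            t0 = time.perf_counter()
            cfg = DipfConfig(n_iter=max(dipf_iteration_grid))
            res = dipf(s.b_obs, s.mask, cfg, record_iters=dipf_iteration_grid)
            for it in dipf_iteration_grid:
                bg = res.snapshots[it]  # type: ignore[attr-defined]
                corr = FieldMap(s.b_obs.grid, np.where(m, s.b_obs.values - bg.values, 0.0))
                rows.append(
                    {
                        "filter": "DIPF",
                        "param": it,
                        "sample": i,
                        "norm_error": l1_metric(corr, s.b_ref, s.mask) / norm,
                        "wall_time_s": time.perf_counter() - t0,
                    }
                )

        if include_chain:
            for order in sphinx_orders or [4]:
                for it in dipf_iteration_grid or [50]:
                    t0 = time.perf_counter()
                    cfg = ChainConfig(sphinx_order=order, dipf=DipfConfig(n_iter=it))
                    corr = run_chain(s.b_obs, s.mask, cfg).corrected
                    rows.append(
                        {
                            "filter": "MUBAFIRE",
                            "param": f"order{order}_iter{it}",
                            "sample": i,
                            "norm_error": l1_metric(corr, s.b_ref, s.mask) / norm,
                            "wall_time_s": time.perf_counter() - t0,
                        }
                    )
    return pd.DataFrame(rows)


def correlation_l1_sigma(report: StudyReport) -> float:
    """Pearson correlation between per-record L1 and masked sigma."""
    x = report.records["L1"].to_numpy(dtype=float)
    y = report.records["sigma"].to_numpy(dtype=float)
    if x.size < 3:
        raise InvalidInputError("need at least 3 records for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise InvalidInputError("degenerate variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
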