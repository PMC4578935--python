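"""The MUBAFIRE sequential filter chain and the optional local stage.

The chain removes background field contributions in the order in which their
models are most reliable: first constant offsets and linear gradients (POLF),
then smooth harmonic variations (SPHINX at low order), then remaining
exterior dipole sources (DIPF).  The optional local stage thresholds the
corrected map, grows the excluded set by diagonal-connection and six-neighbor
erosion, and runs a DIPF whose pseudo-susceptibility support is exactly the
excluded pocket — removing, e.g., the dipole field of an air bubble from the
surrounding tissue while discarding the non-representative voxels themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import FieldMap, InvalidInputError, Mask
from .filters import DipfConfig, dipf, polf, sphinx_filter


@dataclass
class ChainConfig:
    """Parameters of the full chain.

    n_sigma is the threshold multiplier of the local stage: voxels with
    |corrected field| > n_sigma * sigma(corrected field inside the mask) are
    excluded.  Typical values are 5 to 15.
    """

    sphinx_order: int = 4
    dipf: DipfConfig = dc_field(default_factory=DipfConfig)
    local_enabled: bool = False
    n_sigma: float = 8.0
    local_dipf: DipfConfig = dc_field(default_factory=DipfConfig)

    def __post_init__(self) -> None:
        if self.sphinx_order < 1:
            raise InvalidInputError("sphinx_order must be >= 1")
        if self.n_sigma <= 0:
            raise InvalidInputError("n_sigma must be > 0")


@dataclass
class ChainResult:
    corrected: FieldMap
    stage_backgrounds: dict[str, FieldMap]
    excluded_mask: Mask
    refined_mask: Mask
    polf_coeffs: np.ndarray | None = None
    threshold_hz: float | None = None


def threshold_mask(
    fieldmap: FieldMap, mask: Mask, n_sigma: float
) -> tuple[Mask, float]:
    """Flag masked voxels whose |field| exceeds ``xi = n_sigma * sigma``.

    sigma is the standard deviation of the field inside the mask; the
    returned threshold xi is in Hz.
    """
    mask.require_nonempty()
    vals = fieldmap.values[mask.values]
    xi = float(n_sigma) * float(vals.std(ddof=0))
    bad = mask.values & (np.abs(fieldmap.values) > xi)
    return Mask(mask.grid, bad), xi


def _shift(a: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a boolean volume by an integer offset, zero-filling edges."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for o, n in zip(offset, a.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = a[tuple(src)]
    return out


_AXES = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def connect_and_erode(bad: Mask, mask: Mask) -> Mask:
    """Grow the exclusion set by diagonal connection, then 6-neighbor erosion.

    Step 1: any two excluded voxels that are diagonal neighbors (differing by
    one step along each of two axes, e.g. [i,j,k] and [i+1,j+1,k]) get the two
    face-bridging voxels ([i+1,j,k] and [i,j+1,k]) added so that they form a
    face-connected group; voxels differing along all three axes get the three
    single-axis bridges.  Step 2: every in-mask face neighbor of the grown set
    is added ("erosion" of the retained mask).
    """
    if (bad.values & ~mask.values).any():
        raise InvalidInputError("bad mask must be contained in the VOI mask")
    b = bad.values
    grown = b.copy()
    offs: list[np.ndarray] = []
    for sx in (1, -1):
        for sy in (1, -1):
            offs.append(np.array([sx, sy, 0]))
            offs.append(np.array([sx, 0, sy]))
            offs.append(np.array([0, sx, sy]))
            for sz in (1, -1):
                offs.append(np.array([sx, sy, sz]))
    for w in offs:
        pair = b & _shift(b, tuple(-w))  # voxel p with partner at p + w
        if not pair.any():
            continue
        for axis in range(3):
            if w[axis] != 0:
                comp = np.zeros(3, dtype=int)
                comp[axis] = w[axis]
                grown |= _shift(pair, tuple(comp))
    dilated = grown.copy()
    for ax in _AXES:
        dilated |= _shift(grown, ax) | _shift(grown, tuple(-np.array(ax)))
    return Mask(mask.grid, dilated & mask.values)


def run_local(
    fieldmap: FieldMap, mask: Mask, config: ChainConfig
) -> tuple[FieldMap, FieldMap, Mask, Mask, float]:
    """Local outlier stage on an already chain-corrected field.

    Returns (corrected, local_background, excluded, refined_mask, xi).
    The DIPF pseudo-susceptibility support is exactly the excluded voxel set
    and the data term is evaluated on mask minus exclusion; excluded voxels
    are reported as missing (masked out), not inpainted.
    """
    bad, xi = threshold_mask(fieldmap, mask, config.n_sigma)
    excluded = connect_and_erode(bad, mask)
    refined = Mask(mask.grid, mask.values & ~excluded.values)
    if not refined.values.any():
        raise InvalidInputError("local exclusion covers the entire mask")
    if not excluded.values.any():
        zero = FieldMap(mask.grid, np.zeros(mask.grid.shape))
        return fieldmap, zero, excluded, refined, xi
    res = dipf(
        fieldmap,
        mask,
        config.local_dipf,
        support=excluded,
        fit_mask=refined,
    )
    corrected = np.where(refined.values, fieldmap.values - res.background.values, 0.0)
    return FieldMap(mask.grid, corrected), res.background, excluded, refined, xi


def run_chain(fieldmap: FieldMap, mask: Mask, config: ChainConfig | None = None) -> ChainResult:
    """POLF -> SPHINX -> DIPF (-> optional local stage).

    Each stage operates on the residual of the previous one; all stage
    backgrounds are retained so that
    ``input - sum(stage backgrounds) == corrected`` on the refined mask.
    """
    config = config or ChainConfig()
    mask.require_nonempty()
    m = mask.values

    coeffs, bg_polf = polf(fieldmap, mask)
    r1 = FieldMap(fieldmap.grid, np.where(m, fieldmap.values - bg_polf.values, 0.0))

    bg_sphinx, _ = sphinx_filter(r1, mask, config.sphinx_order)
    r2 = FieldMap(fieldmap.grid, np.where(m, r1.values - bg_sphinx.values, 0.0))

    dipf_res = dipf(r2, mask, config.dipf)
    r3 = FieldMap(
        fieldmap.grid, np.where(m, r2.values - dipf_res.background.values, 0.0)
    )

    stages = {"polf": bg_polf, "sphinx": bg_sphinx, "dipf": dipf_res.background}
    excluded = Mask(mask.grid, np.zeros(mask.grid.shape, dtype=bool))
    refined = mask
    corrected = r3
    xi = None
    if config.local_enabled:
        corrected, bg_local, excluded, refined, xi = run_local(r3, mask, config)
        stages["local"] = bg_local
    return ChainResult(
        corrected=corrected,
        stage_backgrounds=stages,
        excluded_mask=excluded,
        refined_mask=refined,
        polf_coeffs=coeffs,
        threshold_hz=xi,
    )
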