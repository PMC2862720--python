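"""Expression-level statistic from a segmented IHC field.

The expression level of a biomarker in one microscope field is the
product of two quantities computed on the SP/NSP/BG label mask:

* staining ratio — area fraction of stained cell pixels among all cell
  pixels, |SP| / (|SP| + |NSP|); background is excluded so the statistic
  does not depend on cell density;
* staining intensity — the mean of a scalar staining signal in [0, 1]
  over SP pixels.

Fields are aggregated per biomarker channel as an unweighted arithmetic
mean over at least ``min_fields`` fields (default 5, matching practice of
scoring several 400x fields along a channel). For cross-method comparison,
expression values are normalized by the per-biomarker mean.

The staining-signal scalar is configurable because "intensity" of a DAB
precipitate has no single canonical pixel definition:

* ``"darkness"`` (default): 1 - luminance/255 with luminance the RGB
  mean; parameter-free and monotone in stain darkness.
* ``"dab_od"``: the DAB channel of standard color-deconvolution
  (optical-density projection on the DAB stain vector), clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hed

from .errors import ConfigurationError, UndefinedFieldError
from .gmm import BG, NSP, SP

SIGNALS = ("darkness", "dab_od")


@dataclass
class ExpressionResult:
    staining_ratio: float
    staining_intensity: float
    expression_level: float
    n_sp: int
    n_nsp: int
    n_bg: int
    signal: str = "darkness"
    no_sp_flag: bool = False


@dataclass
class FieldSet:
    fields: list[ExpressionResult]
    mean_expression: float
    magnification: str = "400x"


def staining_ratio(mask: np.ndarray) -> float:
    """|SP| / (|SP| + |NSP|); raises if the field has no cell pixels."""
    mask = np.asarray(mask)
    n_sp = int((mask == SP).sum())
    n_nsp = int((mask == NSP).sum())
    if n_sp + n_nsp == 0:
        raise UndefinedFieldError("field contains no cell pixels (SP + NSP empty)")
    return n_sp / (n_sp + n_nsp)


def staining_signal(image: np.ndarray, signal: str = "darkness") -> np.ndarray:
    """Per-pixel scalar staining signal in [0, 1] for an 8-bit RGB image."""
    img = np.asarray(image, dtype=float)
    if signal == "darkness":
        return 1.0 - img.mean(axis=-1) / 255.0
    if signal == "dab_od":
        dab = rgb2hed(img / 255.0)[..., 2]
        return np.clip(dab, 0.0, 1.0)
    raise ConfigurationError(f"unknown staining signal {signal!r}; choose from {SIGNALS}")


def staining_intensity(image: np.ndarray, mask: np.ndarray, signal: str = "darkness") -> float:
    """Mean staining signal over SP pixels; 0 if the mask has no SP pixels."""
    mask = np.asarray(mask)
    sp = mask == SP
    if not sp.any():
        return 0.0
    return float(staining_signal(image, signal)[sp].mean())


def expression_level(
    image: np.ndarray, mask: np.ndarray, signal: str = "darkness"
) -> ExpressionResult:
    """Staining ratio x staining intensity with the components recorded."""
    mask = np.asarray(mask)
    ratio = staining_ratio(mask)
    n_sp = int((mask == SP).sum())
    intensity = staining_intensity(image, mask, signal)
    return ExpressionResult(
        staining_ratio=ratio,
        staining_intensity=intensity,
        expression_level=ratio * intensity,
        n_sp=n_sp,
        n_nsp=int((mask == NSP).sum()),
        n_bg=int((mask == BG).sum()),
        signal=signal,
        no_sp_flag=(n_sp == 0),
    )


def aggregate_fields(
    results: list[ExpressionResult], min_fields: int = 5, magnification: str = "400x"
) -> FieldSet:
    """Unweighted mean expression over fields of one biomarker channel."""
    if len(results) < min_fields:
        raise ConfigurationError(
            f"need at least {min_fields} fields per channel, got {len(results)}"
        )
    mean = float(np.mean([r.expression_level for r in results]))
    return FieldSet(fields=list(results), mean_expression=mean, magnification=magnification)


def normalize_by_biomarker_mean(matrix, biomarkers=None):
    """Divide each biomarker column by its mean so column means become 1.

    ``matrix`` is methods x biomarkers (array or DataFrame). Used to put
    different staining methods on a common scale before variance
    comparison.
    """
    import pandas as pd

    df = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    col_means = values.mean(axis=0)
    names = (
        list(matrix.columns) if df
        else (biomarkers if biomarkers is not None else [str(i) for i in range(values.shape[1])])
    )
    for j, mu in enumerate(col_means):
        if mu == 0:
            raise ConfigurationError(f"biomarker {names[j]!r} has zero mean expression")
    out = values / col_means
    if df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
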