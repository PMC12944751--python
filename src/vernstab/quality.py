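"""Sugar-beet processing-quality traits.

Molasses sugar (MS), white sugar content (WSC) and white sugar yield (WSY)
are derived from laboratory measurements of sugar content (SC, % fresh
mass), the melassigenic impurities Na+, K+ and alpha-amino nitrogen
(meq per 100 g fresh mass) and root yield (RY, t/ha):

    MS  = 0.0343 (K + Na) + 0.094 N - 0.31        [%]
    WSC = SC - (MS + 0.6)                          [%]
    WSY = WSC/100 * RY                             [t/ha]

Impurities are stored in meq/100 g; ppm values (as reported by many labs)
are converted explicitly via the equivalent masses of the analytes.
"""

from __future__ import annotations

import numpy as np

#: ppm of fresh mass corresponding to 1 meq/100 g, per analyte
PPM_PER_MEQ = {
    "Na": 230.0,  # 23 mg/meq * 10 (per 100 g -> per kg)
    "K": 391.0,
    "N": 140.0,  # alpha-amino N
}


def _check_nonneg(name, value):
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def molasses_sugar(k, na, amino_n):
    """Molasses sugar (%) from impurity concentrations in meq/100 g."""
    _check_nonneg("k", k)
    _check_nonneg("na", na)
    _check_nonneg("amino_n", amino_n)
    return 0.0343 * (np.asarray(k, dtype=float) + np.asarray(na, dtype=float)) + 0.094 * np.asarray(
        amino_n, dtype=float
    ) - 0.31


def white_sugar_content(sc, ms):
    """White (extractable) sugar content (%) after the molasses deduction."""
    _check_nonneg("sc", sc)
    return np.asarray(sc, dtype=float) - np.asarray(ms, dtype=float) - 0.6


def white_sugar_yield(wsc, ry):
    """White sugar yield (t/ha); WSC enters as a percentage of root mass."""
    _check_nonneg("ry", ry)
    return np.asarray(wsc, dtype=float) / 100.0 * np.asarray(ry, dtype=float)


def ppm_to_meq(value, analyte: str):
    """Convert an impurity from ppm fresh mass to meq/100 g."""
    if analyte not in PPM_PER_MEQ:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {sorted(PPM_PER_MEQ)}")
    _check_nonneg("value", value)
    return np.asarray(value, dtype=float) / PPM_PER_MEQ[analyte]


def meq_to_ppm(value, analyte: str):
    """Inverse of :func:`ppm_to_meq`."""
    if analyte not in PPM_PER_MEQ:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {sorted(PPM_PER_MEQ)}")
    _check_nonneg("value", value)
    return np.asarray(value, dtype=float) * PPM_PER_MEQ[analyte]


def derive_quality(df, sc="sc", na="na", k="k", amino_n="n", ry="ry"):
    """Append ms, wsc, wsy columns to a plot table (impurities in meq/100 g)."""
    out = df.copy()
    out["ms"] = molasses_sugar(out[k], out[na], out[amino_n])
    out["wsc"] = white_sugar_content(out[sc], out["ms"])
    out["wsy"] = white_sugar_yield(out["wsc"], out[ry])
    return out
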