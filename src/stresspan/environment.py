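"""Standardization of raw environmental measurements into stress gradients.

Four raw variables (temperature, rainfall, pH, salinity) are turned into four
dimensionless stress axes (heat, aridity, acidity, salinity) with a common
orientation: higher values mean more stressful conditions.  Rainfall and pH
are reversed (stress occurs at LOW rainfall and LOW pH), and salinity is
log-transformed as ln(x + 0.01) before standardization because field salinity
measurements contain exact zeroes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: mapping from conventional raw column names to stress-axis names
DEFAULT_STRESS_NAMES = {
    "ph": "acidity",
    "rainfall": "aridity",
    "temperature": "heat",
    "salinity": "salinity",
}

#: stress axes in canonical column order
STRESS_COLUMNS = ("acidity", "aridity", "heat", "salinity")


def standardize_environment(
    raw: pd.DataFrame,
    reverse: set[str] | frozenset[str] = frozenset({"ph", "rainfall"}),
    log_transform: set[str] | frozenset[str] = frozenset({"salinity"}),
    sample_col: str = "sample_id",
    rename: dict[str, str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardize raw per-soil-sample environment variables into stress gradients.

    Each variable is (optionally log-transformed, then) centred to mean 0 and
    scaled to SD 1 across soil samples; reversed variables are negated after
    standardization so that high values always mean high stress.

    Parameters
    ----------
    raw
        One row per soil sample.  Must contain ``sample_col`` plus numeric
        environment columns.
    reverse
        Columns whose scale is reversed (negated) after standardization.
    log_transform
        Columns transformed as ``ln(x + 0.01)`` before standardization; values
        must be non-negative.
    rename
        Optional raw-column -> stress-axis name mapping; defaults to
        :data:`DEFAULT_STRESS_NAMES` for columns it covers.
    ddof
        Delta degrees of freedom for the SD (1 = sample SD).

    Returns
    -------
    DataFrame with ``sample_id`` plus one standardized column per input
    variable, named by the stress axis.
    """
    if sample_col not in raw.columns:
        raise ValueError(f"missing sample column {sample_col!r}")
    if len(raw) < 2:
        raise ValueError("need at least 2 soil samples to standardize")
    value_cols = [c for c in raw.columns if c != sample_col]
    if not value_cols:
        raise ValueError("no environment columns found")
    names = dict(DEFAULT_STRESS_NAMES)
    if rename:
        names.update(rename)

    out = pd.DataFrame({"sample_id": raw[sample_col].to_numpy()})
    for col in value_cols:
        x = np.asarray(raw[col], dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"non-finite values in column {col!r}")
        if col in log_transform:
            if np.any(x < 0):
                raise ValueError(f"negative values in log-transformed column {col!r}")
            x = np.log(x + 0.01)
        sd = x.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        z = (x - x.mean()) / sd
        if col in reverse:
            z = -z
        out[names.get(col, col)] = z
    return out


def stress_matrix(profile: pd.DataFrame) -> np.ndarray:
    """Return the (n_samples, 4) stress array in canonical column order."""
    return profile.loc[:, list(STRESS_COLUMNS)].to_numpy(dtype=float)
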