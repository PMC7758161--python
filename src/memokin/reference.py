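"""Published per-volunteer parameter estimates for the heavy-water cohort.

The study cohort that motivates this package comprised eight volunteers
who drank deuterated water for seven weeks; five of them (DW01, DW02,
DW04, DW10, DW11) also had single-telomere-length (STELA) measurements
and received the joint label + telomere fit, per lineage (CD4, CD8).
This module ships the published best-fit table — estimates and asymptotic
standard errors in percent per day, plus the reported self-renewal
percentage — as a reference dataset, together with the published
per-lineage median rows.

DW04 had too few data points for standard errors ("N/D", stored as NaN),
and its mR printed as 0.00 %/day, which forces a self-renewal
contribution of exactly 100%.

These numbers are *inputs* for consistency checks (e.g. recomputing the
self-renewal column or the median rows) and anchor the default truths of
the synthetic-data generator; nothing in the package fits to them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_reference_estimates",
    "load_reference_medians",
    "reference_median_parameters",
]

_COLUMNS = [
    "volunteer_id", "lineage",
    "p1", "se_p1", "z1", "se_z1", "p2", "se_p2", "z2", "se_z2",
    "mR", "se_mR", "self_renewal",
]

_ND = np.nan

# all rates in % per day; self_renewal in %
_ROWS = [
    # CD4 lineage
    ("DW01", "CD4", 0.33, 0.04, 0.88, 0.27, 0.59, 0.08, 1.24, 0.37, 0.02, 0.01, 97),
    ("DW02", "CD4", 0.65, 0.06, 1.89, 0.31, 2.08, 0.23, 3.77, 0.58, 0.17, 0.03, 93),
    ("DW04", "CD4", 0.53, _ND, 1.43, _ND, 0.53, _ND, 1.65, _ND, 0.00, _ND, 100),
    ("DW10", "CD4", 0.58, 0.05, 1.80, 0.28, 0.49, 0.05, 0.92, 0.22, 0.00, 0.00, 99),
    ("DW11", "CD4", 0.44, 0.06, 1.24, 0.33, 1.64, 0.02, 5.24, 0.66, 0.45, 0.02, 79),
    # CD8 lineage
    ("DW01", "CD8", 0.26, 0.02, 0.73, 0.13, 0.40, 0.03, 0.70, 0.13, 0.02, 0.00, 96),
    ("DW02", "CD8", 0.22, 0.02, 0.86, 0.22, 0.42, 0.04, 0.45, 0.19, 0.04, 0.01, 92),
    ("DW04", "CD8", 0.37, _ND, 0.91, _ND, 0.37, _ND, 0.62, _ND, 0.00, _ND, 100),
    ("DW10", "CD8", 0.55, 0.17, 3.60, 1.53, 0.34, 0.11, 0.63, 0.56, 0.02, 0.02, 95),
    ("DW11", "CD8", 0.07, 0.01, 0.24, 0.34, 0.32, 0.03, 0.81, 0.04, 0.07, 0.01, 83),
]

# the published median rows (estimate columns only), % per day / %
_MEDIANS = {
    "CD4": {"p1": 0.53, "z1": 1.43, "p2": 0.59, "z2": 1.65, "mR": 0.02,
            "self_renewal": 97},
    "CD8": {"p1": 0.26, "z1": 0.86, "p2": 0.37, "z2": 0.63, "mR": 0.02,
            "self_renewal": 95},
}


def load_reference_estimates() -> pd.DataFrame:
    """Per-volunteer published estimates (rates in % per day)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def load_reference_medians() -> pd.DataFrame:
    """Published per-lineage median rows (rates in % per day)."""
    records = [{"lineage": lin, **vals} for lin, vals in _MEDIANS.items()]
    return pd.DataFrame.from_records(records)


def reference_median_parameters(lineage: str) -> dict:
    """Published median rates for one lineage, converted to per day.

    Keys p1, z1s, p2, z2s, mR — directly usable for
    :class:`~memokin.kinetics.KineticParameters` (z* identified with the
    published z columns).
    """
    med = _MEDIANS[lineage]
    return {
        "p1": med["p1"] / 100.0, "z1s": med["z1"] / 100.0,
        "p2": med["p2"] / 100.0, "z2s": med["z2"] / 100.0,
        "mR": med["mR"] / 100.0,
    }
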