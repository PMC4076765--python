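"""Internal design-matrix assembly shared by both behavioural models."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_model import CovariateSchema
from .trend_surface import TREND_NAMES, CoordinateScaler, trend_matrix


def covariate_matrix(
    records: Sequence, schema: CovariateSchema, scaler: CoordinateScaler
) -> np.ndarray:
    """(n, p) matrix: encoded covariates followed by the six trend terms.

    Trend terms use the record's stored CBD distance (which may be network
    based) and the supplied coordinate scaler.
    """
    E = np.array([schema.encode(r.covariates) for r in records]).reshape(
        len(records), schema.n_encoded
    )
    xy = np.array([r.home_xy for r in records], dtype=float).reshape(-1, 2)
    cbd = np.array([r.cbd_distance_km for r in records], dtype=float)
    return np.hstack([E, trend_matrix(xy, scaler, cbd)])


def design_names(schema: CovariateSchema) -> tuple[str, ...]:
    return (*schema.encoded_names, *TREND_NAMES)
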