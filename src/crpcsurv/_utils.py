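"""Shared conventions: calendar arithmetic and seeding helpers."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

#: One "month" everywhere a month-denominated window or survival time appears.
#: A single convention avoids off-by-a-few-days disagreements between modules.
DAYS_PER_MONTH = 30.4375


def months_to_days(months: float) -> int:
    """Round a month-denominated window to whole days."""
    return int(round(months * DAYS_PER_MONTH))


def days_to_months(days) -> np.ndarray | float:
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH


def as_date(x) -> pd.Timestamp:
    return pd.Timestamp(x).normalize()


def child_seed(seed: int, stream: str) -> int:
    """Derive a per-stage seed (< 2**31) deterministically from a master seed."""
    # crc32 (not builtin hash) so the derivation is stable across processes
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stream))
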