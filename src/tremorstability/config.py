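"""Run configuration.

All analysis parameters live in a single frozen dataclass.  ``paper_mode``
(the default) locks the parameters that define the published analysis chain
— 0.1 Hz third-order detrend, 2–9 Hz peak search, f_c ± 2 Hz band, 1 s
envelope smoothing, type-7 IQR quantiles, the 1.05 Hz decision threshold and
the 1000/10000 bootstrap iteration counts — so that two runs with the same
inputs are guaranteed comparable.  Set ``paper_mode=False`` in the same
``replace`` call to experiment with alternatives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .exceptions import ConfigurationError

#: parameters whose defaults define the canonical analysis; immutable in paper mode
LOCKED_PARAMS = frozenset(
    {
        "detrend_corner_hz",
        "filter_order",
        "peak_search_hz",
        "band_halfwidth_hz",
        "smooth_window_s",
        "quantile_rule",
        "fixed_threshold",
        "duration_iterations",
        "compare_iterations",
        "cv_folds",
    }
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the TSI analysis chain.

    Frequencies in Hz, durations in seconds.
    """

    detrend_corner_hz: float = 0.1      # high-pass trend-correction corner
    filter_order: int = 3               # Butterworth order (each pass)
    peak_search_hz: tuple[float, float] = (2.0, 9.0)
    band_halfwidth_hz: float = 2.0      # tremor band is f_c +/- this
    smooth_window_s: float = 1.0        # envelope moving-average window
    edge_margin_s: float = 1.0          # filter-edge margin excluded from crossings
    segment_start_s: float = 0.0
    segment_duration_s: float = 100.0   # analysis window length
    welch_segment_s: float = 8.0        # Welch segment length (Hann, 50% overlap)
    mhp_log_base: float = 10.0          # base of the log in the MHP formula
    quantile_rule: str = "linear"       # numpy interpolation method for the IQR
    fixed_threshold: float = 1.05       # TSI decision cutoff (> ET, <= PD)
    snr_cap_db: float = 240.0           # ceiling when the residual envelope vanishes
    plausibility_margin_hz: float = 0.5  # cycle guard beyond the analysis band
    duration_iterations: int = 1000
    compare_iterations: int = 10000
    cv_folds: int = 10
    ci_method: str = "hanley"           # "hanley" or "delong" AUC confidence interval
    paper_mode: bool = True

    def replace(self, **overrides) -> "AnalysisConfig":
        """Return a copy with ``overrides`` applied.

        Raises ConfigurationError when attempting to override a locked
        parameter while ``paper_mode`` remains in force.
        """
        paper_mode = overrides.get("paper_mode", self.paper_mode)
        if paper_mode:
            locked = LOCKED_PARAMS.intersection(overrides)
            changed = {k for k in locked if overrides[k] != getattr(type(self)(), k)}
            if changed:
                raise ConfigurationError(
                    f"paper_mode forbids overriding {sorted(changed)}; "
                    "pass paper_mode=False to change them"
                )
        return dataclasses.replace(self, **overrides)


DEFAULT_CONFIG = AnalysisConfig()
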