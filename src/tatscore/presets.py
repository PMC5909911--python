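"""Named parameter presets.

Two fitted parameter sets for twice-daily fluticasone/salmeterol ship as
presets: one fitted against monthly adverse-event (exacerbation) rates in
a COPD-validated model, one fitted against daily peak expiratory flow in
an uncontrolled-asthma cohort.  Both correspond to half-lives near the
12-hour dosing interval, so their thresholds read directly as the
fraction of the current dose needed under perfect adherence.
"""

from __future__ import annotations

from .model import ModelParams

__all__ = ["COPD_AE", "ASTHMA_PEFR", "PRESETS"]

#: Fitted against monthly adverse-event rate (alpha 0.056 /h, half-life
#: 12.4 h; beta 73; theta 0.69).
COPD_AE = ModelParams(alpha=0.056, beta=73.0, theta=0.69)

#: Fitted against daily peak expiratory flow (alpha 0.062 /h, half-life
#: 11.2 h; beta 63; theta 0.56; outcome lag tau 18.2 h).
ASTHMA_PEFR = ModelParams(alpha=0.062, beta=63.0, theta=0.56, tau=18.2)

PRESETS: dict[str, ModelParams] = {
    "copd-ae": COPD_AE,
    "asthma-pefr": ASTHMA_PEFR,
}
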