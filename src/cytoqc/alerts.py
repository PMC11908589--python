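"""Quality-control alert signalling.

Alerts are first-class outcomes of the method, not programming errors: a
calibration that produces indistinguishable references, or a search whose
valid set is empty, must surface to the operator (and to the CLI exit code)
rather than silently degrade.
"""

from __future__ import annotations


class QcWarning(UserWarning):
    """Non-fatal quality signal (degenerate feature, sampling shortfall...)."""


class QcAlert(Exception):
    """A hard quality-control alert.

    Raised when the method's own validity conditions fail: an empty valid
    combination set during parameter search, or a reference weight of zero
    (two pipelines indistinguishable).  Carries a machine-readable code.
    """

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


# Machine-readable alert codes used across reports and the CLI.
ALERT_SMALL_ALPHA = "SMALL_ALPHA"
ALERT_ZERO_ALPHA = "ZERO_ALPHA"
ALERT_SATURATED_ALPHA = "SATURATED_ALPHA"
ALERT_DIAGONAL = "DIAGONAL_CONSTRAINT"
ALERT_EMPTY_VALID_SET = "EMPTY_VALID_SET"
ALERT_EMPTY_STABLE_SET = "EMPTY_STABLE_SET"
ALERT_NO_COMPATIBLE_REFERENCE = "NO_COMPATIBLE_REFERENCE"
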