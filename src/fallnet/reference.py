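"""Bundled reference tables for the elderly ADL specificity evaluation.

Two task × subject fraction tables (correct / total ADL trials, NA where a
subject skipped a task) are shipped as plain CSV: the published per-movement
results of the final lightweight model on the elderly ADL cohort under the
single-window decision rule, and under the modified three-consecutive-window
rule.  Pooling their cells reproduces the headline specificities of that
evaluation (562/640 → 87.81% and 627/640 → 97.97%).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .errors import ConfigError
from .evaluation import FractionTable, read_fraction_table

_FILES = {
    "single": "elderly_adl_fractions_single_window.csv",
    "consecutive": "elderly_adl_fractions_consecutive_window.csv",
}


def reference_table_path(rule: str = "single") -> Path:
    """Filesystem path of a bundled fraction table (rule: single|consecutive)."""
    if rule not in _FILES:
        raise ConfigError(f"rule must be one of {sorted(_FILES)}, got {rule!r}")
    return Path(resources.files("fallnet") / "data" / _FILES[rule])


def reference_fraction_table(rule: str = "single") -> FractionTable:
    """Load a bundled elderly-ADL fraction table."""
    return read_fraction_table(reference_table_path(rule))
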