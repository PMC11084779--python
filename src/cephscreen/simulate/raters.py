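"""Synthetic repeated-measurement tables for reliability analysis.

Emulates the reliability protocol of the screening workflow: a subgroup of
subjects measured by several raters, generated under the two-way
crossed-random-effects model y_ij = mu + s_i + r_j + e_ij, whose
absolute-agreement intraclass correlation is
var_subject / (var_subject + var_rater + var_error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidSpecError


@dataclass
class RaterSpec:
    """Subjects x raters measurement-table specification.

    Variance components are in squared measurement units; ``grand_mean``
    shifts every entry and does not affect the ICC.
    """

    n_subjects: int = 20
    n_raters: int = 2
    var_subject: float = 9.0
    var_rater: float = 0.5
    var_error: float = 0.5
    grand_mean: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2:
            raise InvalidSpecError("need at least 2 subjects and 2 raters")
        if min(self.var_subject, self.var_rater, self.var_error) < 0:
            raise InvalidSpecError("variance components must be >= 0")
        if self.var_subject + self.var_error <= 0:
            raise InvalidSpecError("var_subject + var_error must be > 0")

    @property
    def true_icc(self) -> float:
        """Population ICC (absolute agreement, single rater)."""
        total = self.var_subject + self.var_rater + self.var_error
        return self.var_subject / total


def generate_rater_table(spec: RaterSpec | None = None):
    """Draw a subjects x raters table; returns ``(DataFrame, true_icc)``."""
    import pandas as pd

    spec = spec or RaterSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = rng.normal(0.0, np.sqrt(spec.var_subject), size=spec.n_subjects)
    r = rng.normal(0.0, np.sqrt(spec.var_rater), size=spec.n_raters)
    e = rng.normal(0.0, np.sqrt(spec.var_error),
                   size=(spec.n_subjects, spec.n_raters))
    y = spec.grand_mean + s[:, None] + r[None, :] + e
    df = pd.DataFrame(
        y,
        index=[f"subject_{i+1}" for i in range(spec.n_subjects)],
        columns=[f"rater_{j+1}" for j in range(spec.n_raters)],
    )
    return df, spec.true_icc
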