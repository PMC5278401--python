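"""Relatedness classes and their expected Rxy values.

Three classes are distinguished: unrelated pairs, first-order relatives
(parent-offspring or full siblings, r = 0.5) and second-order relatives
(half siblings, avuncular or grandparental pairs, r = 0.25). When genotypes
are reduced to a single allele per locus ("forced homozygote"), only half of
each genome is interrogated and the expected Queller-Goodnight coefficient
halves: 0.5 -> 0.25 for first order, 0.25 -> 0.125 for second order.
"""

from __future__ import annotations

import enum

__all__ = ["RelatednessClass"]

_DIPLOID_EXPECTATION = {
    "UNRELATED": 0.0,
    "FIRST_ORDER": 0.5,
    "SECOND_ORDER": 0.25,
}


class RelatednessClass(enum.Enum):
    """A relatedness class with its expected diploid and forced Rxy."""

    UNRELATED = "UNRELATED"
    FIRST_ORDER = "FIRST_ORDER"
    SECOND_ORDER = "SECOND_ORDER"

    @property
    def label(self) -> str:
        return self.value

    @property
    def expected_diploid_rxy(self) -> float:
        """Expected Rxy when full diploid genotypes are used."""
        return _DIPLOID_EXPECTATION[self.value]

    @property
    def expected_forced_rxy(self) -> float:
        """Expected Rxy after forcing one allele per locus (half the diploid value)."""
        return _DIPLOID_EXPECTATION[self.value] / 2.0
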