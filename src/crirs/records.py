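"""Chemical identity records tying hazard and exposure profiles together."""

from __future__ import annotations

import re
from dataclasses import dataclass

from .exposure import ExposureProfile
from .hazard import HazardProfile

__all__ = ["ChemicalRecord", "cas_checksum_ok", "format_cas"]

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def cas_checksum_ok(cas: str) -> bool:
    """Validate a CAS registry number's mod-10 check digit.

    The check digit is the weighted sum of the other digits (weights 1, 2,
    3, ... from the rightmost non-check digit leftward) modulo 10. Returns
    False for strings that do not even match the NNNNNNN-NN-N shape.
    """
    m = _CAS_RE.match(cas.strip())
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    total = sum((i + 1) * int(d) for i, d in enumerate(digits))
    return total % 10 == int(m.group(3))


def format_cas(base_digits: str) -> str:
    """Append the correct check digit to an 4–9 digit CAS base and format it."""
    if not base_digits.isdigit() or not 4 <= len(base_digits) <= 9:
        raise ValueError(f"CAS base must be 4-9 digits, got {base_digits!r}")
    check = sum((i + 1) * int(d) for i, d in enumerate(base_digits[::-1])) % 10
    return f"{base_digits[:-2]}-{base_digits[-2:]}-{check}"


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity plus the hazard and exposure profiles of one chemical."""

    name: str
    cas: str
    hazard: HazardProfile
    exposure: ExposureProfile

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("chemical name must be non-empty")
        if not self.cas or not self.cas.strip():
            raise ValueError(f"CAS string must be non-empty (chemical {self.name!r})")
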