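"""Adapter/linker specifications.

DNase Hi-C protocols that mark ligation junctions use short biotinylated
oligonucleotides: a two-part ~7 bp "bridge" adapter in older protocols, or a
single ~19 bp linker in BAT-Hi-C-style protocols.  The published protocols do
not fix universal sequences, so adapters are supplied by the user; the
presets below bundle *synthetic* example sequences of the right lengths for
simulation and testing, together with the incidental-match rates typically
assumed for each length class (``c ~ 0.05`` for a 7-mer, ``c ~ 0`` for a
19-mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AdapterError(ValueError):
    """Invalid adapter specification."""


@dataclass(frozen=True)
class AdapterSpec:
    """An adapter sequence and its matching parameters.

    Parameters
    ----------
    name : str
        Label used in pattern strings and reports.
    sequence : str
        Adapter sequence, A/C/G/T only.
    min_overlap : int
        Minimum length of a non-internal (end-anchored) partial match.
    max_error_rate : float
        Allowed mismatch fraction; with the default 0 matching is exact.
        A rate r allows ``floor(r * match_length)`` mismatches, so any rate
        below ``1 / match_length`` is effectively exact.
    """

    name: str
    sequence: str
    min_overlap: int = 5
    max_error_rate: float = 0.0
    incidental_rate: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - set("ACGT"):
            raise AdapterError(f"adapter {self.name!r}: sequence must be non-empty A/C/G/T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < self.min_overlap:
            raise AdapterError(
                f"adapter {self.name!r}: length {len(seq)} < min_overlap {self.min_overlap}"
            )
        if not 0.0 <= self.max_error_rate < 1.0:
            raise AdapterError("max_error_rate must be in [0, 1)")

    def __len__(self) -> int:  # convenience for span arithmetic
        return len(self.sequence)


# Synthetic stand-in sequences (not from any published protocol): a 7-bp
# bridge-style adapter and a 19-bp single-linker-style adapter.
BRIDGE7 = AdapterSpec("bridge7", "GCTGAGG", incidental_rate=0.05)
LINKER19 = AdapterSpec("linker19", "GCTGAGGGATCCTAACGCT", incidental_rate=0.0)

PRESETS: dict[str, AdapterSpec] = {a.name: a for a in (BRIDGE7, LINKER19)}


def get_adapter(preset_or_sequence: str, name: str = "adapter") -> AdapterSpec:
    """Resolve a preset name or a raw sequence into an :class:`AdapterSpec`."""
    key = preset_or_sequence.lower()
    if key in PRESETS:
        return PRESETS[key]
    return AdapterSpec(name, preset_or_sequence)
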