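"""Small sequence helpers shared across modules."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_CONST = "I"  # Q40; qualities carry no information in this toolkit


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(seq: str, motif: str) -> list[int]:
    """All start positions of exact (possibly overlapping) motif occurrences."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits
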