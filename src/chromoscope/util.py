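"""Small shared helpers."""

from __future__ import annotations

import re


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key ordering chromosome names numerically where possible.

    chr1 < chr2 < chr10 < chrX; purely lexicographic for non-numeric parts.
    """
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)
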