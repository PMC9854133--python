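"""Lightweight HGVS protein-change normalization.

Only what alteration matching needs: three-letter amino-acid codes are
collapsed to one-letter (p.His1047Arg -> p.H1047R), ``Ter`` becomes ``*``,
enclosing parentheses are dropped and the ``p.`` prefix is made canonical.
No validation against transcript databases is attempted.
"""

from __future__ import annotations

import re

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}

_AA3_RE = re.compile("|".join(_AA3_TO_1))


def normalize_protein_change(hgvs_p: str | None) -> str | None:
    """Return a canonical one-letter form of a protein change, or None.

    >>> normalize_protein_change("p.His1047Arg")
    'p.H1047R'
    >>> normalize_protein_change("p.(Lys662Ter)")
    'p.K662*'
    >>> normalize_protein_change("p.H1047R")
    'p.H1047R'
    """
    if hgvs_p is None:
        return None
    s = hgvs_p.strip()
    if not s:
        return None
    if s.lower().startswith("p."):
        s = s[2:]
    s = s.strip("()")
    s = _AA3_RE.sub(lambda m: _AA3_TO_1[m.group(0)], s)
    return "p." + s
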