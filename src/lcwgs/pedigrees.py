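"""Hand-built example pedigrees.

Small deterministic pedigrees used for analytic kinship checks and for
replicate studies of the kinship-corrected frequency estimator.
"""

from __future__ import annotations

import numpy as np

from .simulate import PedigreeTable


def textbook_pedigree() -> PedigreeTable:
    """Three generations covering the textbook kinship relationships.

    F1xF2 -> A, B, C (full sibs); F3xF4 -> D; D x A -> E, G (B is E's
    aunt, F1 is E's grandparent); F5 x B -> H (H and E are first
    cousins); F5 x F6 -> I (H and I are half sibs).
    """
    ids = ["F1", "F2", "F3", "F4", "F5", "F6"]
    fa: list[str | None] = [None] * 6
    mo: list[str | None] = [None] * 6
    sex = [1, 2, 1, 2, 1, 2]

    def add(i: str, f: str, m: str, s: int) -> None:
        ids.append(i)
        fa.append(f)
        mo.append(m)
        sex.append(s)

    add("A", "F1", "F2", 2)
    add("B", "F1", "F2", 2)
    add("C", "F1", "F2", 1)
    add("D", "F3", "F4", 1)
    add("E", "D", "A", 1)
    add("G", "D", "A", 2)
    add("H", "F5", "B", 1)
    add("I", "F5", "F6", 2)
    pops = ["A" if f is None else None for f in fa]
    return PedigreeTable(ids, fa, mo, np.array(sex), pops)


def unbalanced_pedigree() -> PedigreeTable:
    """Three-generation pedigree with very unequal sibship sizes.

    One founder couple has six children, the others two and one; the large
    sibships make the naive allele-frequency estimator visibly biased
    relative to the kinship-weighted (BLUE) one.
    """
    ids: list[str] = []
    fa: list[str | None] = []
    mo: list[str | None] = []
    sex: list[int] = []

    def add(i: str, f: str | None, m: str | None, s: int) -> None:
        ids.append(i)
        fa.append(f)
        mo.append(m)
        sex.append(s)

    for k, s in zip(range(1, 7), [1, 2, 1, 2, 1, 2]):
        add(f"F{k}", None, None, s)
    for k in range(6):
        add(f"C1{k}", "F1", "F2", 1 if k % 2 else 2)
    for k in range(2):
        add(f"C2{k}", "F3", "F4", 1 if k % 2 else 2)
    add("C30", "F5", "F6", 1)
    for k in range(4):
        add(f"D1{k}", "C11", "C20", 1 if k % 2 else 2)
    for k in range(2):
        add(f"D2{k}", "C30", "C10", 1 if k % 2 else 2)
    pops = ["A" if f is None else None for f in fa]
    return PedigreeTable(ids, fa, mo, np.array(sex), pops)
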