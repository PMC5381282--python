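"""Shared test utilities: matrix builders and an independent
predicate-based category oracle.

The oracle re-derives each category definition in isolation (set
algebra, no shared code with the package's ordered decision procedure)
and asserts that, after the multi-het precedence rule, at most one
specific predicate fires; sites matching none fall to the residuals
(I with a het present, U without).
"""

from __future__ import annotations

import numpy as np

from limerad import DEFAULT_ACCESSIONS, GenotypeMatrix

# the standard IUPAC two-allele table, restated independently
HET = {
    "M": "AC",
    "R": "AG",
    "W": "AT",
    "S": "CG",
    "Y": "CT",
    "K": "GT",
}
HOMS = "ACGT"
TEN_CODES = tuple(HOMS) + tuple(HET)

ACC = list(DEFAULT_ACCESSIONS)
B_IDX = [0, 1, 2, 3]
I_IDX = [4, 5, 6, 7]


def mat(patterns, accessions=None, site_ids=None) -> GenotypeMatrix:
    """Build a matrix from per-site pattern strings like 'MMMM MAMA'
    (spaces ignored), one string per site."""
    rows = [list(p.replace(" ", "")) for p in patterns]
    return GenotypeMatrix(
        accession_ids=list(accessions or ACC),
        calls=np.array(rows, dtype="U1"),
        site_ids=site_ids,
    )


def oracle_classify(calls, b_idx=B_IDX, i_idx=I_IDX) -> str:
    calls = [str(c) for c in calls]
    B = [calls[k] for k in b_idx]
    I = [calls[k] for k in i_idx]
    hets = sorted({c for c in calls if c in HET})

    if len(hets) >= 2:
        return "L"

    def uni(group):
        return len(set(group)) == 1

    def all_hom(group):
        return all(c in HOMS for c in group)

    preds = {
        "A": uni(calls) and calls[0] in HET,
        "B": uni(B) and uni(I) and all_hom(B) and all_hom(I) and B[0] != I[0],
        "C": uni(B) and B[0] in HET and uni(I) and all_hom(I),
        "D": uni(I) and I[0] in HET and uni(B) and all_hom(B),
        "J": all_hom(calls) and uni(B) and not uni(I) and B[0] in I,
        "K": all_hom(calls) and uni(I) and not uni(B),
    }
    if len(hets) == 1:
        h = hets[0]
        allowed = set(HET[h]) | {h}
        within = lambda g: all(c in allowed for c in g)
        preds["E"] = uni(B) and B[0] == h and not uni(I) and within(I)
        preds["F"] = uni(I) and I[0] == h and not uni(B) and within(B)
        preds["G"] = uni(B) and all_hom(B) and not uni(I) and h in I and within(I)
        preds["H"] = uni(I) and all_hom(I) and not uni(B) and h in B and within(B)

    fired = [lab for lab in "ABCDEFGHJK" if preds.get(lab)]
    assert len(fired) <= 1, f"non-exclusive predicates {fired} for {calls}"
    if fired:
        return fired[0]
    return "I" if hets else "U"


def random_call_vectors(n: int, rng: np.random.Generator, width: int = 8):
    """Yield ``n`` complete, informative call vectors: half uniform over
    the ten codes, half confined to one het code and its resolutions
    (the biallelic shape real data takes)."""
    out = []
    codes = np.array(TEN_CODES)
    hets = list(HET)
    while len(out) < n:
        if rng.random() < 0.5:
            v = codes[rng.integers(0, len(codes), size=width)]
        else:
            h = hets[rng.integers(0, len(hets))]
            pool = np.array([h, *HET[h]])
            v = pool[rng.integers(0, len(pool), size=width)]
        v = [str(c) for c in v]
        has_het = any(c in HET for c in v)
        if not has_het and len(set(v)) < 2:
            continue  # monomorphic hom: not genotypable
        out.append(v)
    return out
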