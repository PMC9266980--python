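"""Disease over-representation tests for cell-type-specific miRNA sets.

Two complementary questions per (cell type, disease) pair:

* is the cell type's signature enriched for miRNAs associated with the
  disease?  Upper-tail hypergeometric test, Benjamini-Hochberg corrected
  across diseases within each cell type, significant at q < 0.05.
* are the disease's *causal* miRNAs over-represented in the signature?
  One-sided (greater) Fisher's exact test on the 2x2 in-signature x causal
  table over the universe, restricted to diseases with at least 5 causal
  miRNAs to avoid poorly annotated diseases.

The universe defaults to the intersection of measured miRNAs and annotated
miRNAs, which avoids inflating enrichment with miRNAs that could never
have been observed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrix import ValidationError, warn_data
from .specificity import SignatureCatalog

DEFAULT_FDR = 0.05
DEFAULT_MIN_CAUSAL = 5


def hypergeom_enrich(
    signature: set[str],
    disease_sets: dict[str, set[str]],
    universe: set[str],
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each disease set in one
    signature, BH-corrected across diseases.

    Signature members outside the universe are dropped with a warning;
    disease sets are silently intersected with the universe.
    """
    if not universe:
        raise ValidationError("empty universe")
    outside = signature - universe
    if outside:
        warn_data(
            f"dropped {len(outside)} signature member(s) outside the universe"
        )
    sig = signature & universe
    N = len(universe)
    rows = []
    for disease, dset in disease_sets.items():
        dset = dset & universe
        K = len(dset)
        n = len(sig)
        overlap = sig & dset
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K and n else 1.0
        rows.append(
            {
                "disease": disease,
                "overlap": k,
                "signature_size": n,
                "disease_size": K,
                "universe_size": N,
                "p": min(p, 1.0),
                "members": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "disease", "overlap", "signature_size", "disease_size",
            "universe_size", "p", "members",
        ],
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = []
        out["significant"] = []
    return out


def enrich_catalog(
    catalog: SignatureCatalog,
    disease_sets: dict[str, set[str]],
    universe: set[str],
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Hypergeometric enrichment for every cell type in the catalog.

    The BH family is per cell type across diseases (each signature's
    disease scan is corrected on its own).
    """
    frames = []
    for cell_type, sig in catalog.sets().items():
        res = hypergeom_enrich(sig, disease_sets, universe, fdr=fdr)
        res.insert(0, "cell_type", cell_type)
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def fisher_causal(
    signature: set[str],
    causal: set[str],
    universe: set[str],
    min_causal: int = DEFAULT_MIN_CAUSAL,
) -> dict | None:
    """One-sided Fisher's exact test: signature membership vs causality.

    Returns None when the disease has fewer than ``min_causal`` causal
    miRNAs in the universe.  The odds ratio is the sample OR with a
    Haldane-Anscombe 0.5 correction when a zero cell occurs (display only;
    the p-value is never corrected).  Degenerate margins give p = 1.
    """
    if not universe:
        raise ValidationError("empty universe")
    sig = signature & universe
    cau = causal & universe
    if len(cau) < min_causal:
        return None
    a = len(sig & cau)
    b = len(sig - cau)
    c = len(cau - sig)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = 1.0
    else:
        _, p = scipy.stats.fisher_exact(table, alternative="greater")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return {
        "in_sig_causal": a,
        "in_sig_noncausal": b,
        "out_sig_causal": c,
        "out_sig_noncausal": d,
        "odds_ratio": float(odds),
        "p": float(p),
    }


def causal_association(
    catalog: SignatureCatalog,
    causal_sets: dict[str, set[str]],
    universe: set[str],
    min_causal: int = DEFAULT_MIN_CAUSAL,
) -> pd.DataFrame:
    """Fisher causal-association scan over all (cell type, disease) pairs."""
    rows = []
    for cell_type, sig in catalog.sets().items():
        for disease, cau in causal_sets.items():
            res = fisher_causal(sig, cau, universe, min_causal=min_causal)
            if res is None:
                continue
            rows.append({"cell_type": cell_type, "disease": disease, **res})
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type", "disease", "in_sig_causal", "in_sig_noncausal",
            "out_sig_causal", "out_sig_noncausal", "odds_ratio", "p",
        ],
    )
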