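"""Metabolite-class overrepresentation among hit lists.

Given a hit list (e.g. metabolites that lost rhythmicity, gained it, changed
overall level, or were labelled behaviour-influenced) and the analysis
universe, each chemical class is tested by a Fisher exact test on the 2x2
table [in-hits & in-class, in-hits & out, out & in-class, out & out]. The
default alternative is one-sided "greater" (overrepresentation) and p-values
are reported unadjusted with significance called at p < 0.05; the very small
"other" class is kept in the universe but not tested by default.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io_preprocess import ConcentrationMatrix


def class_overrepresentation(
    hits,
    universe,
    alternative: str = "greater",
    exclude_classes: tuple = ("other",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact overrepresentation test per metabolite class.

    Parameters
    ----------
    hits : iterable of str
        Metabolite ids; must be a subset of the universe.
    universe : ConcentrationMatrix or pandas.Series
        Either a concentration matrix (its class labels are used) or a Series
        mapping metabolite_id -> class.
    alternative : {"greater", "two-sided", "less"}
        Sidedness of the Fisher test; overrepresentation is one-sided greater.
    exclude_classes : tuple of str
        Classes kept in the universe but not tested (too small to be
        meaningful by default).

    Returns one row per tested class with the 2x2 counts, ``p`` and
    ``significant`` (p < alpha, unadjusted). An empty hit list yields p = 1
    for every class.
    """
    classes = universe.metabolite_class if isinstance(universe, ConcentrationMatrix) \
        else pd.Series(universe)
    hits = set(hits)
    unknown = hits - set(classes.index)
    if unknown:
        raise ValueError(f"hit(s) not in universe: {sorted(unknown)[:5]}")
    n_universe = len(classes)
    n_hits = len(hits)
    rows = []
    for cls, members in classes.groupby(classes):
        if cls in exclude_classes:
            continue
        in_class = set(members.index)
        a = len(hits & in_class)
        b = n_hits - a
        c = len(in_class) - a
        d = n_universe - n_hits - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append({
            "class_name": cls,
            "hits_in_class": a,
            "hits_total": n_hits,
            "class_size": len(in_class),
            "universe": n_universe,
            "p": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows).set_index("class_name").sort_values("p")
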