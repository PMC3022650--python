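"""Reaction-set comparison across models by functional category.

Reactions are matched by a canonical stoichiometry signature by default
(metabolite ids sorted, coefficients normalized to smallest-integer form,
direction-insensitive), since reaction ids are not comparable across models;
id-based matching is available by flag. The report counts, per category and
per model, total reactions, reactions unique to that model, the percentage
unique, and the number of reactions common to all models.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

import pandas as pd

from .model import SUBSYSTEMS, Model


def canonical_signature(stoichiometry: dict[str, float]) -> tuple:
    """Direction-insensitive smallest-integer canonical form of a reaction."""
    items = sorted(stoichiometry.items())
    fracs = [Fraction(c).limit_denominator(10**6) for _, c in items]
    denom_lcm = 1
    for f in fracs:
        denom_lcm = denom_lcm * f.denominator // gcd(denom_lcm, f.denominator)
    ints = [int(f * denom_lcm) for f in fracs]
    g = 0
    for n in ints:
        g = gcd(g, abs(n))
    if g:
        ints = [n // g for n in ints]
    sig = tuple((mid, n) for (mid, _), n in zip(items, ints))
    neg = tuple((mid, -n) for mid, n in sig)
    return min(sig, neg)


@dataclass
class ComparisonReport:
    per_category: pd.DataFrame  # index: category; columns: (model, total|unique|pct_unique)
    totals: pd.DataFrame  # per-model totals row
    common: int  # reactions present in every model

    def to_table(self) -> pd.DataFrame:
        table = self.per_category.copy()
        table.loc["Total reactions"] = self.totals.iloc[0]
        table["common"] = ""
        return table


def _signatures(model: Model, match_on: str) -> dict:
    """Map signature -> subsystem for each non-pseudo reaction of a model."""
    special = {model.biomass_reaction_id, model.atpm_reaction_id}
    out = {}
    for r in model.reactions:
        if r.id in special:
            continue
        key = r.id if match_on == "id" else canonical_signature(r.stoichiometry)
        out[key] = r.subsystem
    return out


def compare_models(models: list[Model], match_on: str = "stoichiometry") -> ComparisonReport:
    """Compare >=2 models at the reaction level.

    Unique = present in exactly one model (duplicated models in the input list
    are collapsed first, so the counts are invariant under duplication and
    reordering)."""
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if match_on not in ("stoichiometry", "id"):
        raise ValueError(f"unknown match rule {match_on!r}")

    # collapse duplicate models (same reaction signature set)
    sigs = []
    seen_sets = []
    labels = []
    for m in models:
        s = _signatures(m, match_on)
        key = frozenset(s)
        if key in seen_sets:
            continue
        seen_sets.append(key)
        sigs.append(s)
        labels.append(m.id)

    all_keys = [frozenset(s) for s in sigs]
    common_keys = frozenset.intersection(*all_keys)
    categories = list(SUBSYSTEMS)

    columns = {}
    totals = {}
    for label, s, keys in zip(labels, sigs, all_keys):
        others = [k for lab, k in zip(labels, all_keys) if lab != label]
        if others:
            unique_keys = keys - frozenset.union(*others)
        else:
            # every input model was a copy of this one: nothing is unique
            unique_keys = frozenset()
        total_per_cat = {c: 0 for c in categories}
        unique_per_cat = {c: 0 for c in categories}
        for key, cat in s.items():
            total_per_cat[cat] += 1
            if key in unique_keys:
                unique_per_cat[cat] += 1
        columns[(label, "total")] = total_per_cat
        columns[(label, "unique")] = unique_per_cat
        columns[(label, "pct_unique")] = {
            c: (100.0 * unique_per_cat[c] / total_per_cat[c]) if total_per_cat[c] else 0.0
            for c in categories
        }
        totals[(label, "total")] = len(keys)
        totals[(label, "unique")] = len(unique_keys)
        totals[(label, "pct_unique")] = 100.0 * len(unique_keys) / len(keys) if keys else 0.0

    per_cat = pd.DataFrame(columns).reindex(categories)
    per_cat.columns = pd.MultiIndex.from_tuples(per_cat.columns)
    totals_df = pd.DataFrame([totals])
    totals_df.columns = pd.MultiIndex.from_tuples(totals_df.columns)
    return ComparisonReport(per_cat, totals_df, len(common_keys))
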