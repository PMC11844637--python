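"""Scoring demultiplexer outputs against simulation truth and each other.

A *call set* is a per-barcode table of calls: a donor id (singlet call),
"doublet", or "unassigned". Truth comes from the simulator (singlet(k),
doublet(k1,k2), empty). Metrics:

* droplet-type accuracy — the fraction of shared barcodes whose predicted
  category matches truth. A truth singlet is correct when the method calls
  *some* donor; a truth doublet when it calls doublet; a truth empty when
  the method refuses a singlet call (doublet or unassigned) — the most
  charitable consistent reading, since empties carry no donor.
* singleton-donor accuracy — among truth singlets the method called as some
  donor, the fraction assigned the right donor (``strict=True`` divides by
  all truth singlets instead, mixing in detection failures).
* label harmonization — genotype-free methods emit anonymous clusters;
  optimal assignment on the cluster x donor contingency table maps them to
  donors before donor-level metrics apply.
* between-method correlation and multi-way intersections — the agreement
  statistics behind ensemble-demultiplexing skepticism.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import contingency

NON_SINGLET = ("doublet", "unassigned")


def truth_from_simulation(truth_frame: pd.DataFrame, donor_ids: list[str]) -> pd.DataFrame:
    """Convert a simulator truth table (barcode, droplet_type, donor_1 index)
    into the metric-facing truth schema (barcode, droplet_type, donor_id)."""
    out = truth_frame[["barcode", "droplet_type"]].copy()
    out["donor_id"] = [
        donor_ids[i] if t == "singlet" else None
        for t, i in zip(truth_frame["droplet_type"], truth_frame["donor_1"])
    ]
    return out


def _check_calls(calls: pd.DataFrame, name: str = "calls") -> pd.DataFrame:
    if calls["barcode"].duplicated().any():
        raise ValueError(f"duplicate barcodes in {name}")
    return calls.set_index("barcode")


def _truth_category(truth: pd.DataFrame) -> pd.Series:
    """Truth droplet_type column ('singlet'/'doublet'/'empty'), indexed by barcode."""
    t = _check_calls(truth, "truth")
    return t["droplet_type"]


def _call_category(call: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(call.isin(NON_SINGLET), call, "singlet"), index=call.index
    )


def droplet_type_accuracy(calls: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of shared barcodes whose droplet type is called correctly."""
    c = _check_calls(calls)
    t = _truth_category(truth)
    shared = c.index.intersection(t.index)
    if len(shared) == 0:
        raise ValueError("no shared barcodes between calls and truth")
    cat = _call_category(c.loc[shared, "call"])
    tt = t.loc[shared]
    ok = (
        ((tt == "singlet") & (cat == "singlet"))
        | ((tt == "doublet") & (cat == "doublet"))
        | ((tt == "empty") & cat.isin(NON_SINGLET))
    )
    return float(ok.mean())


def singleton_donor_accuracy(
    calls: pd.DataFrame, truth: pd.DataFrame, strict: bool = False
) -> float:
    """Fraction of truth singlets assigned the correct donor.

    Denominator: truth singlets the method called as some donor (isolating
    donor-assignment quality); with ``strict`` all truth singlets. Returns
    NaN when the denominator is empty.
    """
    c = _check_calls(calls)
    t = _check_calls(truth, "truth")
    shared = c.index.intersection(t.index)
    tt = t.loc[shared]
    singlets = tt[tt["droplet_type"] == "singlet"]
    call = c.loc[singlets.index, "call"]
    called_donor = ~call.isin(NON_SINGLET)
    denom = len(singlets) if strict else int(called_donor.sum())
    if denom == 0:
        return float("nan")
    correct = int((call[called_donor] == singlets.loc[called_donor, "donor_id"]).sum())
    return correct / denom


def harmonize_labels(
    calls: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Map anonymous cluster labels to donor ids by optimal assignment.

    ``reference`` is a truth table (barcode, donor_id for singlets). The
    cluster x donor contingency table over shared singlet barcodes is solved
    with the Hungarian algorithm (maximising agreement); "doublet" and
    "unassigned" pass through. Raises when there are more clusters than
    donors. Returns the relabelled call set and the cluster -> donor map.
    """
    c = _check_calls(calls)
    t = _check_calls(reference, "reference")
    shared = c.index.intersection(t.index)
    tt = t.loc[shared]
    singlet_truth = tt[tt["droplet_type"] == "singlet"] if "droplet_type" in tt else tt
    call = c.loc[singlet_truth.index, "call"]
    mask = ~call.isin(NON_SINGLET)
    table = pd.crosstab(call[mask], singlet_truth.loc[mask, "donor_id"])
    donors = sorted(singlet_truth["donor_id"].unique())
    clusters = list(table.index)
    if len(clusters) > len(donors):
        raise ValueError(
            f"{len(clusters)} clusters exceed {len(donors)} donors; cannot harmonize"
        )
    cost = -table.reindex(columns=donors, fill_value=0).to_numpy(float)
    ri, ci = linear_sum_assignment(cost)
    mapping = {clusters[i]: donors[j] for i, j in zip(ri, ci)}
    out = calls.copy()
    out["call"] = [
        mapping.get(v, v) if v not in NON_SINGLET else v for v in calls["call"]
    ]
    return out, mapping


def droplet_type_correlation(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, three_level: bool = False
) -> float:
    """Between-method agreement over shared barcodes.

    Default: Pearson correlation of the binary is-singlet indicators (NaN
    when either is constant). ``three_level=True`` computes Cramér's V on
    the full singlet/doublet/unassigned contingency instead.
    """
    a = _check_calls(calls_a, "calls_a")
    b = _check_calls(calls_b, "calls_b")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared barcodes")
    ca = _call_category(a.loc[shared, "call"])
    cb = _call_category(b.loc[shared, "call"])
    if three_level:
        table = pd.crosstab(ca, cb).to_numpy()
        return float(contingency.association(table, method="cramer"))
    xa = (ca == "singlet").to_numpy(float)
    xb = (cb == "singlet").to_numpy(float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(np.corrcoef(xa, xb)[0, 1])


def multiway_intersection(call_sets: dict[str, pd.DataFrame]) -> dict:
    """Agreement structure across >= 2 call sets.

    Returns: ``pairwise`` droplet-type overlap matrix (fraction of shared
    barcodes with equal category), ``all_type_proportion`` / and
    ``all_donor_proportion`` (fraction of barcodes common to every set that
    agree on category / on exact singlet donor across all sets), and
    ``membership_counts`` — UpSet-style counts of every called-singlet
    pattern over the common barcodes.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least 2 call sets")
    names = list(call_sets)
    indexed = {n: _check_calls(df, n) for n, df in call_sets.items()}
    cats = {n: _call_category(d["call"]) for n, d in indexed.items()}

    pairwise = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        shared = cats[a].index.intersection(cats[b].index)
        frac = float((cats[a].loc[shared] == cats[b].loc[shared]).mean()) if len(shared) else np.nan
        pairwise.loc[a, b] = pairwise.loc[b, a] = frac

    common = cats[names[0]].index
    for n in names[1:]:
        common = common.intersection(cats[n].index)
    cat_frame = pd.DataFrame({n: cats[n].loc[common] for n in names})
    all_type = float(cat_frame.nunique(axis=1).eq(1).mean()) if len(common) else np.nan
    call_frame = pd.DataFrame({n: indexed[n].loc[common, "call"] for n in names})
    all_singlet = (cat_frame == "singlet").all(axis=1)
    all_donor = (
        float((call_frame[all_singlet].nunique(axis=1) == 1).mean())
        if int(all_singlet.sum())
        else np.nan
    )

    membership = (
        (cat_frame == "singlet")
        .groupby(names)
        .size()
        .rename("n_barcodes")
        .reset_index()
        if len(common)
        else pd.DataFrame(columns=[*names, "n_barcodes"])
    )
    return {
        "pairwise": pairwise,
        "all_type_proportion": all_type,
        "all_donor_proportion": all_donor,
        "membership_counts": membership,
    }
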