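"""Protein-domain expansion testing on a domain-by-species gene-count table.

A domain is called expanded in exactly one species when that species
(i) holds the unique largest gene number (GN), (ii) max/second-max GN
exceeds 1.2, (iii) max minus second-max exceeds 3, and (iv) max over
the mean GN of the remaining species exceeds 1.5.  All inequalities are
strict; ties for the maximum fail.  An optional focal mode tests a
chosen species against only the non-focal species, which is how a
domain can come out expanded in two focal species at once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RATIO_SECOND = 1.2
DIFF_SECOND = 3
RATIO_MEAN = 1.5


@dataclass(frozen=True)
class ExpansionVerdict:
    domain_id: str
    expanded_in: str | None
    max_gn: int
    second_gn: int
    ratio_second: float
    diff_second: int
    ratio_mean: float


def _evaluate(domain_id: str, species: list[str], gn: np.ndarray) -> ExpansionVerdict:
    order = np.argsort(gn, kind="stable")[::-1]
    mx, second = int(gn[order[0]]), int(gn[order[1]])
    others_mean = float(np.mean(np.delete(gn, order[0])))
    ratio_second = mx / second if second else math.inf
    ratio_mean = mx / others_mean if others_mean else math.inf
    unique_max = int((gn == mx).sum()) == 1
    passes = (
        unique_max
        and ratio_second > RATIO_SECOND
        and (mx - second) > DIFF_SECOND
        and ratio_mean > RATIO_MEAN
    )
    return ExpansionVerdict(
        domain_id,
        species[order[0]] if passes else None,
        mx,
        second,
        ratio_second,
        mx - second,
        ratio_mean,
    )


def expansion_test(counts: dict[str, int], domain_id: str = "") -> ExpansionVerdict:
    """Apply the four expansion criteria to one domain's per-species GNs."""
    if len(counts) < 2:
        raise ValueError("need gene numbers for at least 2 species")
    species = list(counts)
    gn = np.array([counts[s] for s in species])
    if (gn < 0).any():
        raise ValueError("gene numbers must be non-negative")
    if not gn.any():
        warnings.warn(f"domain {domain_id or '<?>'}: all gene numbers are zero")
        return ExpansionVerdict(domain_id, None, 0, 0, math.nan, 0, math.nan)
    return _evaluate(domain_id, species, gn)


def scan_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-domain verdicts for a table indexed by domain with one GN
    column per species."""
    rows = []
    species = list(table.columns)
    for domain_id, row in table.iterrows():
        v = expansion_test({s: int(row[s]) for s in species}, str(domain_id))
        rows.append(
            {
                "domain_id": v.domain_id,
                "expanded_in": v.expanded_in,
                "max_gn": v.max_gn,
                "second_gn": v.second_gn,
                "ratio_second": v.ratio_second,
                "diff_second": v.diff_second,
                "ratio_mean": v.ratio_mean,
            }
        )
    return pd.DataFrame(rows)


def expanded_by_species(table: pd.DataFrame) -> dict[str, list[str]]:
    scan = scan_table(table)
    out: dict[str, list[str]] = {s: [] for s in table.columns}
    for _, row in scan.iterrows():
        if row["expanded_in"] is not None:
            out[row["expanded_in"]].append(row["domain_id"])
    return out


def focal_expansion_test(
    counts: dict[str, int], focal: str, domain_id: str = ""
) -> bool:
    """Interpretation mode: does the focal species pass all four criteria
    against the non-focal species only?  Lets several focal species
    (e.g., two congeners) each qualify for the same domain."""
    others = {s: n for s, n in counts.items() if s != focal}
    if not others:
        raise ValueError("need at least one non-focal species")
    mx = counts[focal]
    second = max(others.values())
    mean_others = sum(others.values()) / len(others)
    ratio_second = mx / second if second else math.inf
    ratio_mean = mx / mean_others if mean_others else math.inf
    return (
        mx > second
        and ratio_second > RATIO_SECOND
        and (mx - second) > DIFF_SECOND
        and ratio_mean > RATIO_MEAN
    )
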