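"""NSAF scoring and presence/absence target calling for affinity proteomics.

The normalized spectral abundance factor of protein i in one replicate is

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)

where SpC is the spectral count and L the protein length in residues; NSAF
sums to 1 per replicate.  Candidate targets are called by the reproducible
presence rule used in affinity-enrichment experiments: detected in at least
``min_present_reps`` treated replicates with at most ``control_max`` total
counts across control replicates, ranked by mean treated NSAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedResultError

__all__ = ["SpectralCountTable", "nsaf", "call_enriched"]


@dataclass
class SpectralCountTable:
    """Protein x replicate spectral counts with per-condition replicate groups.

    ``data`` columns: ``protein``, ``length``, then one integer column per
    replicate; ``conditions`` maps a condition name to its replicate columns.
    """

    data: pd.DataFrame
    conditions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "protein" not in self.data.columns or "length" not in self.data.columns:
            raise ValueError("table needs 'protein' and 'length' columns")
        if (self.data["length"] <= 0).any():
            raise ValueError("protein lengths must be positive")
        all_reps = [c for cols in self.conditions.values() for c in cols]
        if len(all_reps) != len(set(all_reps)):
            raise ValueError("replicate labels must be unique")
        for col in all_reps:
            counts = self.data[col]
            if (counts < 0).any() or not np.allclose(counts, counts.round()):
                raise ValueError(f"counts in {col!r} must be non-negative integers")

    @property
    def replicates(self) -> list[str]:
        return [c for cols in self.conditions.values() for c in cols]

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, conditions: dict[str, list[str]]) -> "SpectralCountTable":
        return cls(pd.read_csv(path, sep="\t"), conditions)


def nsaf(table: SpectralCountTable, replicate: str, scale: float = 1.0) -> pd.Series:
    """Per-protein NSAF for one replicate; values sum to ``scale``.

    ``scale`` is a display multiplier only (e.g. 1e5) and does not affect
    ranking or calling.
    """
    if replicate not in table.replicates:
        raise ValueError(f"replicate {replicate!r} not in table")
    saf = table.data[replicate] / table.data["length"]
    total = saf.sum()
    if total <= 0:
        raise UndefinedResultError(f"replicate {replicate!r} has all-zero counts")
    out = scale * saf / total
    out.index = table.data["protein"]
    return out


def call_enriched(
    table: SpectralCountTable,
    treated: str,
    control: str,
    min_present_reps: int = 3,
    control_max: int = 0,
    nsaf_scale: float = 1.0,
) -> pd.DataFrame:
    """Candidate targets present in treated replicates and absent from controls.

    Returns a DataFrame (protein, n_present_treated, control_total,
    mean_nsaf, sd_nsaf) ranked by mean treated NSAF descending.
    """
    for cond in (treated, control):
        if cond not in table.conditions:
            raise ValueError(f"condition {cond!r} not in table")
    t_cols = table.conditions[treated]
    c_cols = table.conditions[control]
    if len(t_cols) < min_present_reps:
        raise ValueError(
            f"condition {treated!r} has {len(t_cols)} replicates "
            f"(< min_present_reps={min_present_reps})")
    present = (table.data[t_cols] > 0).sum(axis=1)
    control_total = table.data[c_cols].sum(axis=1)
    mask = (present >= min_present_reps) & (control_total <= control_max)
    nsaf_mat = pd.concat(
        [nsaf(table, col, nsaf_scale) for col in t_cols], axis=1)
    nsaf_mat.columns = t_cols
    rows = []
    for i in np.flatnonzero(mask.to_numpy()):
        protein = table.data["protein"].iloc[i]
        vals = nsaf_mat.loc[protein].to_numpy(dtype=float)
        rows.append({
            "protein": protein,
            "n_present_treated": int(present.iloc[i]),
            "control_total": int(control_total.iloc[i]),
            "mean_nsaf": float(vals.mean()),
            "sd_nsaf": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        })
    out = pd.DataFrame(
        rows, columns=["protein", "n_present_treated", "control_total",
                       "mean_nsaf", "sd_nsaf"])
    return out.sort_values("mean_nsaf", ascending=False).reset_index(drop=True)
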