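"""Stage-2 ranking by hydrogen-bond-propensity difference (ΔHBP).

For a target T and coformer C, every donor–acceptor pairing carries a
propensity in [0, 1] (the probability that the pairing is realized in a
crystal).  The multicomponent score is

    ΔHBP = max P(T–C)  −  max( max P(T–T), max P(C–C) )

i.e. the best heteromeric propensity minus the best homomeric one; positive
values favour cocrystallization.  Propensities are *inputs* here — real ones
come from models trained on curated crystal-structure data — but a logistic
surrogate is provided so the full pipeline runs end-to-end on synthetic
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROPENSITY_COLUMNS = ["donor_group", "acceptor_group", "mol_a", "mol_b", "propensity"]


@dataclass
class PropensityTable:
    """Donor–acceptor propensities, one row per (donor group, acceptor group,
    molecule pair).  ``entries`` is a DataFrame with columns
    donor_group / acceptor_group / mol_a / mol_b / propensity."""

    entries: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        missing = [c for c in PROPENSITY_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"propensity table missing columns: {missing}")
        p = self.entries["propensity"]
        if ((p < 0) | (p > 1)).any():
            bad = self.entries[(p < 0) | (p > 1)]
            raise ValueError(
                f"propensities outside [0, 1]:\n{bad.to_string(index=False)}"
            )

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "PropensityTable":
        return cls(pd.read_csv(path, sep="\t"), provenance or str(path))

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def pair_propensities(self, mol_a: str, mol_b: str) -> pd.DataFrame:
        e = self.entries
        m = ((e["mol_a"] == mol_a) & (e["mol_b"] == mol_b)) | (
            (e["mol_a"] == mol_b) & (e["mol_b"] == mol_a)
        )
        return e[m]


@dataclass
class HBPScore:
    coformer: str
    p_het_max: float
    p_homo_max: float
    best_het_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def delta(self) -> float:
        return self.p_het_max - self.p_homo_max


def _validated(values) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1)):
        raise ValueError(f"propensity outside [0, 1]: {arr}")
    return arr


def delta_hbp(p_het, p_tt=(), p_cc=(), coformer: str = "",
              het_pairs=None) -> HBPScore:
    """ΔHBP from raw propensity sets.

    ``p_het`` must be non-empty; empty homomeric sets are treated as
    propensity 0 (logged, most permissive convention).  ``het_pairs`` may give
    the (donor, acceptor) label of each heteromeric entry so that all
    maximizing pairs are reported on ties.
    """
    het = _validated(p_het)
    if het.size == 0:
        raise ValueError("heteromeric propensity set must be non-empty")
    tt = _validated(p_tt)
    cc = _validated(p_cc)
    if tt.size == 0 and cc.size == 0:
        log.info("no homomeric propensities for %s: homomeric max taken as 0", coformer)
    p_homo = max(tt.max() if tt.size else 0.0, cc.max() if cc.size else 0.0)
    p_het_max = float(het.max())
    best = []
    if het_pairs is not None:
        best = [
            tuple(het_pairs[i])
            for i in range(len(het))
            if abs(het[i] - p_het_max) < 1e-12
        ]
    return HBPScore(
        coformer=coformer,
        p_het_max=p_het_max,
        p_homo_max=float(p_homo),
        best_het_pairs=best,
    )


def score_from_table(
    table: PropensityTable, target: str, coformer: str
) -> HBPScore:
    het = table.pair_propensities(target, coformer)
    tt = table.pair_propensities(target, target)
    cc = table.pair_propensities(coformer, coformer)
    return delta_hbp(
        het["propensity"].to_numpy(),
        tt["propensity"].to_numpy(),
        cc["propensity"].to_numpy(),
        coformer=coformer,
        het_pairs=list(zip(het["donor_group"], het["acceptor_group"])),
    )


def score_all(table: PropensityTable, target: str) -> list[HBPScore]:
    e = table.entries
    others = sorted(
        set(e.loc[e["mol_a"] == target, "mol_b"])
        | set(e.loc[e["mol_b"] == target, "mol_a"])
    )
    return [score_from_table(table, target, c) for c in others if c != target]


def rank_coformers(scores) -> pd.DataFrame:
    """Rank by ΔHBP descending with a stable name tie-break.

    Accepts a list of :class:`HBPScore` or a DataFrame with columns
    ``coformer`` and ``delta`` (extra columns pass through).  The returned
    frame carries ``rank`` (1-based) and a ``sign`` partition column; the
    counts of positive / zero / negative scores are stored in
    ``frame.attrs["partition"]``.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "coformer": s.coformer,
                    "p_het_max": s.p_het_max,
                    "p_homo_max": s.p_homo_max,
                    "delta": s.delta,
                }
                for s in scores
            ]
        )
    if "delta" not in df.columns or "coformer" not in df.columns:
        raise ValueError("ranking needs 'coformer' and 'delta' columns")
    df = df.sort_values(
        ["delta", "coformer"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["sign"] = np.sign(df["delta"]).astype(int)
    df.attrs["partition"] = {
        "positive": int((df["delta"] > 0).sum()),
        "zero": int((df["delta"] == 0).sum()),
        "negative": int((df["delta"] < 0).sum()),
    }
    return df


# --------------------------------------------------------------------------
# logistic surrogate propensity model


def logistic_propensity(features, coefficients, intercept: float = 0.0) -> float:
    """Surrogate propensity 1/(1+exp(−(β·x + b))) for a donor–acceptor pair
    described by a numeric feature vector."""
    x = np.asarray(features, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    if x.shape != beta.shape:
        raise ValueError(
            f"feature/coefficient dimension mismatch: {x.shape} vs {beta.shape}"
        )
    z = float(x @ beta) + intercept
    return float(1.0 / (1.0 + np.exp(-z)))


def fit_logistic_propensity(X, y):
    """Fit surrogate coefficients on labelled donor–acceptor outcomes
    (scikit-learn logistic regression, unpenalized).  Returns (beta, intercept)."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return clf.coef_.ravel(), float(clf.intercept_[0])
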