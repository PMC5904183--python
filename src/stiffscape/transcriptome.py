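"""Probe-level stiffness-response transcriptome filtering.

Implements a stepwise fold-change filter on exon-array probe sets
(log2 RMA expression): an expression floor, per-probe log2 fold-change
thresholds, a minimum-probe rule for calling genes up/down-regulated,
exclusion of bidirectional genes, knockdown-dependence assessment on the
previously regulated probe IDs, and cross-stimulus set comparison.

The filter is deliberately fold-change-only (no variance moderation):
regulation is a deterministic function of the probe means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "filter_expressed",
    "probe_log2fc",
    "call_genes",
    "GeneCallResults",
    "assess_gata2_dependence",
    "apply_flat_filter",
    "cross_stimulus_overlap",
    "OverlapResult",
    "count_regulated_tfs",
    "StiffnessResponseModel",
]

DEFAULT_FLOOR = 5.0
DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_PROBES = 3


@dataclass
class ProbeMatrix:
    """Probe-level log2 expression values with a sample design.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by a 2-level MultiIndex ``(probe_set_id, gene_id)``,
        one column per sample, values normalized log2 expression.
    design : Mapping[str, str]
        Maps each sample id (column name) to its condition label.
    """

    values: pd.DataFrame
    design: dict

    def __post_init__(self) -> None:
        self.design = dict(self.design)
        if self.values.index.nlevels != 2:
            raise ValueError("values must be indexed by (probe_set_id, gene_id)")
        self.values.index.names = ["probe_set_id", "gene_id"]
        if self.values.index.duplicated().any():
            raise ValueError("duplicate (probe_set_id, gene_id) rows")
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list:
        out = [s for s in self.samples if self.design[s] == condition]
        if not out:
            raise KeyError(f"condition {condition!r} not present in design")
        return out

    @classmethod
    def from_frames(cls, table: pd.DataFrame, design: pd.DataFrame) -> "ProbeMatrix":
        """Build from a flat table (probe_id, gene_id, samples...) and a
        (sample, condition) design table."""
        tab = table.set_index([table.columns[0], table.columns[1]])
        dmap = dict(zip(design.iloc[:, 0].astype(str), design.iloc[:, 1].astype(str)))
        return cls(tab.astype(float), dmap)

    def subset_samples(self, samples: Sequence[str]) -> "ProbeMatrix":
        return ProbeMatrix(self.values[list(samples)].copy(),
                           {s: self.design[s] for s in samples})


def filter_expressed(matrix: ProbeMatrix, floor: float = DEFAULT_FLOOR,
                     conditions: Sequence[str] | None = None) -> ProbeMatrix:
    """Drop probe sets whose mean expression is strictly below ``floor``.

    The mean is computed over the samples of the contrast being analysed
    (``conditions``, if given, restricts to those arms); a probe averaging
    exactly ``floor`` is retained.
    """
    if matrix.values.empty:
        raise ValueError("empty probe matrix")
    if conditions is None:
        cols = matrix.samples
    else:
        cols = [s for c in conditions for s in matrix.samples_for(c)]
    means = matrix.values[cols].mean(axis=1)
    keep = means >= floor
    return ProbeMatrix(matrix.values.loc[keep].copy(), matrix.design)


def probe_log2fc(matrix: ProbeMatrix, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Per-probe log2 fold change: mean(cond_b) − mean(cond_a).

    Values are already log2, so the fold change is a plain difference of
    per-condition replicate means. Returns a frame with columns
    ``probe_set_id, gene_id, log2fc``.
    """
    a = matrix.values[matrix.samples_for(cond_a)].mean(axis=1)
    b = matrix.values[matrix.samples_for(cond_b)].mean(axis=1)
    out = (b - a).rename("log2fc").reset_index()
    return out


def _call_one_gene(fcs: np.ndarray, probe_ids: np.ndarray,
                   threshold: float, min_probes: int) -> dict:
    up = fcs > threshold
    down = fcs < -threshold
    n_up, n_down = int(up.sum()), int(down.sum())
    qual_up = n_up >= min_probes
    qual_down = n_down >= min_probes
    if qual_up and qual_down:
        status = "bidirectional"
        reg_ids, avg = [], np.nan
    elif qual_up:
        status = "up"
        reg_ids, avg = list(probe_ids[up]), float(fcs[up].mean())
    elif qual_down:
        status = "down"
        reg_ids, avg = list(probe_ids[down]), float(fcs[down].mean())
    else:
        status = "unregulated"
        reg_ids, avg = [], np.nan
    return {
        "n_probes_total": len(fcs),
        "n_probes_up": n_up,
        "n_probes_down": n_down,
        "status": status,
        "avg_log2fc_regulated": avg,
        "regulated_probe_ids": reg_ids,
    }


@dataclass
class GeneCallResults:
    """Per-gene regulation verdicts from the stepwise fold-change filter."""

    calls: pd.DataFrame
    threshold: float
    min_probes: int
    params: dict = field(default_factory=dict)

    @property
    def up_genes(self) -> set:
        return set(self.calls.loc[self.calls.status == "up", "gene_id"])

    @property
    def down_genes(self) -> set:
        return set(self.calls.loc[self.calls.status == "down", "gene_id"])

    @property
    def bidirectional_genes(self) -> set:
        return set(self.calls.loc[self.calls.status == "bidirectional", "gene_id"])

    @property
    def n_regulated(self) -> int:
        """Regulated transcripts before bidirectional exclusion."""
        return len(self.up_genes) + len(self.down_genes) + len(self.bidirectional_genes)

    @property
    def bidirectional_fraction(self) -> float:
        """Fraction of regulated genes qualifying in both directions."""
        n = self.n_regulated
        return len(self.bidirectional_genes) / n if n else 0.0

    def regulated_probe_map(self) -> dict:
        """gene_id -> regulated probe ids, for up/down genes only."""
        sub = self.calls[self.calls.status.isin(["up", "down"])]
        return dict(zip(sub.gene_id, sub.regulated_probe_ids))

    def summary(self) -> str:
        lines = [
            "Stiffness-response gene calls",
            "=" * 34,
            f"threshold (|log2FC|):   {self.threshold}",
            f"min regulated probes:   {self.min_probes}",
            f"genes tested:           {len(self.calls)}",
            f"regulated transcripts:  {self.n_regulated}",
            f"  upregulated:          {len(self.up_genes)}",
            f"  downregulated:        {len(self.down_genes)}",
            f"  bidirectional:        {len(self.bidirectional_genes)}"
            f" ({100 * self.bidirectional_fraction:.1f}% of regulated; excluded)",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.calls.copy()
        out["regulated_probe_ids"] = out["regulated_probe_ids"].map(
            lambda ids: ",".join(map(str, ids)))
        return out


def call_genes(probe_fcs: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
               min_probes: int = DEFAULT_MIN_PROBES) -> GeneCallResults:
    """Call genes up/down-regulated from per-probe log2 fold changes.

    A probe is regulated up iff ``log2fc > threshold`` and down iff
    ``log2fc < -threshold`` (strict). A gene is called up (down) iff at
    least ``min_probes`` of its probes are regulated in that direction;
    genes qualifying in both directions are flagged bidirectional and
    excluded from the final up/down lists. ``avg_log2fc_regulated`` is the
    mean fold change over only the qualifying direction's regulated probes.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    records = []
    for gene_id, grp in probe_fcs.groupby("gene_id", sort=True):
        rec = _call_one_gene(grp["log2fc"].to_numpy(dtype=float),
                             grp["probe_set_id"].to_numpy(),
                             threshold, min_probes)
        rec["gene_id"] = gene_id
        records.append(rec)
    cols = ["gene_id", "n_probes_total", "n_probes_up", "n_probes_down",
            "status", "avg_log2fc_regulated", "regulated_probe_ids"]
    calls = pd.DataFrame(records, columns=cols) if records else pd.DataFrame(columns=cols)
    return GeneCallResults(calls=calls, threshold=threshold, min_probes=min_probes)


def assess_gata2_dependence(results: GeneCallResults, kd_probe_fcs: pd.DataFrame,
                            threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Assess knockdown dependence of previously called genes.

    For each up/down-regulated gene, the knockdown-contrast log2 fold
    change is averaged over exactly the probe IDs that drove the original
    call; the gene is *dependent* iff the absolute average exceeds
    ``threshold`` (direction-agnostic). ``concordant_reversal`` marks
    genes whose knockdown shift opposes their stiffness-regulation
    direction. Genes whose probes are absent from the knockdown contrast
    are recorded as unassessable, never dropped.
    """
    kd_map = dict(zip(kd_probe_fcs["probe_set_id"], kd_probe_fcs["log2fc"]))
    dir_sign = {"up": 1.0, "down": -1.0}
    rows = []
    sub = results.calls[results.calls.status.isin(["up", "down"])]
    for _, rec in sub.iterrows():
        fcs = [kd_map[p] for p in rec.regulated_probe_ids if p in kd_map]
        if not fcs:
            rows.append({"gene_id": rec.gene_id, "status": rec.status,
                         "avg_log2fc_kd": np.nan, "dependent": False,
                         "concordant_reversal": False, "assessable": False})
            continue
        avg = float(np.mean(fcs))
        dep = abs(avg) > threshold
        rev = dep and (np.sign(avg) == -dir_sign[rec.status])
        rows.append({"gene_id": rec.gene_id, "status": rec.status,
                     "avg_log2fc_kd": avg, "dependent": dep,
                     "concordant_reversal": bool(rev), "assessable": True})
    cols = ["gene_id", "status", "avg_log2fc_kd", "dependent",
            "concordant_reversal", "assessable"]
    return pd.DataFrame(rows, columns=cols)


def apply_flat_filter(matrix: ProbeMatrix, cond_a: str, cond_b: str,
                      floor: float = DEFAULT_FLOOR,
                      threshold: float = DEFAULT_THRESHOLD) -> tuple[set, set]:
    """Gene-level fold-change filter (no minimum-probe rule).

    The path used for gene-level matrices such as the shear-stress
    comparison set: apply the expression floor, compute per-row mean log2
    fold change ``cond_b`` vs ``cond_a``, and return the (up, down) gene
    sets at the strict ±threshold cut.
    """
    filt = filter_expressed(matrix, floor=floor, conditions=[cond_a, cond_b])
    fcs = probe_log2fc(filt, cond_a, cond_b)
    up = set(fcs.loc[fcs.log2fc > threshold, "gene_id"])
    down = set(fcs.loc[fcs.log2fc < -threshold, "gene_id"])
    return up, down


@dataclass
class OverlapResult:
    """Exact set overlaps between two up/down gene-call sets."""

    n_a_up: int
    n_a_down: int
    n_b_up: int
    n_b_down: int
    shared_up: int
    shared_down: int
    discordant: int

    @property
    def fractions(self) -> dict:
        def frac(k, n):
            return k / n if n else 0.0
        return {
            "shared_up_of_a": frac(self.shared_up, self.n_a_up),
            "shared_up_of_b": frac(self.shared_up, self.n_b_up),
            "shared_down_of_a": frac(self.shared_down, self.n_a_down),
            "shared_down_of_b": frac(self.shared_down, self.n_b_down),
        }

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_a_up", "n_a_down", "n_b_up", "n_b_down",
              "shared_up", "shared_down", "discordant")}
        d["fractions"] = self.fractions
        return d


def cross_stimulus_overlap(a_up: set, a_down: set, b_up: set, b_down: set,
                           id_map: Mapping[str, str] | None = None) -> OverlapResult:
    """Compare two regulation calls by exact gene-identifier intersection.

    ``id_map`` optionally translates the second call set's identifiers to
    the first platform's before intersecting. Discordant genes are those
    regulated in opposite directions in the two sets.
    """
    if id_map is not None:
        b_up = {id_map.get(g, g) for g in b_up}
        b_down = {id_map.get(g, g) for g in b_down}
    return OverlapResult(
        n_a_up=len(a_up), n_a_down=len(a_down),
        n_b_up=len(b_up), n_b_down=len(b_down),
        shared_up=len(a_up & b_up), shared_down=len(a_down & b_down),
        discordant=len(a_up & b_down) + len(a_down & b_up),
    )


def count_regulated_tfs(results: GeneCallResults, tf_list: Iterable[str]) -> int:
    """Number of regulated genes (up ∪ down) present in a transcription
    factor list supplied by the user (no database is bundled)."""
    tfs = set(tf_list)
    if not tfs:
        import warnings
        warnings.warn("empty transcription-factor list", stacklevel=2)
        return 0
    return len((results.up_genes | results.down_genes) & tfs)


class StiffnessResponseModel:
    """Stepwise fold-change model of a stiffness-response array experiment.

    Wraps a :class:`ProbeMatrix` plus the filter parameters; ``fit``
    runs floor filter → per-probe log2FC → gene calling for a contrast
    and returns :class:`GeneCallResults`. ``assess_dependence`` re-uses a
    fit's regulated probe IDs on a knockdown contrast.
    """

    def __init__(self, matrix: ProbeMatrix, floor: float = DEFAULT_FLOOR,
                 threshold: float = DEFAULT_THRESHOLD,
                 min_probes: int = DEFAULT_MIN_PROBES):
        self.matrix = matrix
        self.floor = floor
        self.threshold = threshold
        self.min_probes = min_probes

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, design: pd.DataFrame,
                       **kwargs) -> "StiffnessResponseModel":
        return cls(ProbeMatrix.from_frames(table, design), **kwargs)

    def probe_fcs(self, cond_a: str, cond_b: str) -> pd.DataFrame:
        filt = filter_expressed(self.matrix, floor=self.floor,
                                conditions=[cond_a, cond_b])
        return probe_log2fc(filt, cond_a, cond_b)

    def fit(self, cond_a: str, cond_b: str) -> GeneCallResults:
        res = call_genes(self.probe_fcs(cond_a, cond_b),
                         threshold=self.threshold, min_probes=self.min_probes)
        res.params = {"cond_a": cond_a, "cond_b": cond_b, "floor": self.floor,
                      "threshold": self.threshold, "min_probes": self.min_probes}
        return res

    def assess_dependence(self, results: GeneCallResults, cond_a: str,
                          cond_b: str) -> pd.DataFrame:
        # knockdown contrast uses the full (unfiltered) probe set: the
        # regulated probe IDs were already vetted in the original fit
        kd_fcs = probe_log2fc(self.matrix, cond_a, cond_b)
        return assess_gata2_dependence(results, kd_fcs, threshold=self.threshold)
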