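"""Linkage-disequilibrium operations: pairwise r² and redundancy removal.

Dense genotyping arrays oversample regions of interest, so a single LD block
under the significance threshold can masquerade as enrichment of every gene
it touches.  Two standard remedies are implemented over a reference panel:

* **pruning** — a greedy scan in coordinate order that drops any variant in
  high LD (r² >= threshold) with an already-kept neighbour.  P-values are
  never consulted.
* **clumping** — variants are visited in ascending p-value order; each
  unconsumed variant becomes a lead and consumes its high-LD neighbours, so
  only lead signals survive.

r² is the squared Pearson correlation of genotype dosages, the quantity
PLINK reports for unphased data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import SumStats


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) aligned to variant coordinates.

    Missing dosages are mean-imputed per variant at construction and flagged;
    downstream correlation is then deterministic.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    had_missing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x variants)")
        n_var = self.dosages.shape[1]
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == n_var):
            raise ValueError("variant metadata length does not match dosage columns")
        if len(set(self.snp_ids)) != n_var:
            raise ValueError("duplicate variant ids in panel")
        self.had_missing = np.isnan(self.dosages).any(axis=0)
        if self.had_missing.any():
            col_mean = np.nanmean(self.dosages, axis=0)
            idx = np.where(np.isnan(self.dosages))
            self.dosages[idx] = np.take(col_mean, idx[1])
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        centered = self.dosages - self.dosages.mean(axis=0)
        self._norm = np.sqrt((centered**2).sum(axis=0))
        self._centered = centered

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def monomorphic(self) -> np.ndarray:
        return self._norm == 0.0

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"variant {snp_id!r} not in panel") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_by_index(self, i: int, j: int) -> float:
        ni, nj = self._norm[i], self._norm[j]
        if ni == 0.0 or nj == 0.0:
            raise ValueError("r² undefined for a monomorphic variant")
        r = float(self._centered[:, i] @ self._centered[:, j]) / (ni * nj)
        return r * r


@dataclass(frozen=True)
class PruneConfig:
    r2_max: float = 0.3
    bp_window: int = 1_000_000
    mode: str = "pruning"  # "pruning" | "clumping"

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must be in (0, 1]")
        if self.bp_window <= 0:
            raise ValueError("bp_window must be positive")
        if self.mode not in ("pruning", "clumping"):
            raise ValueError(f"unknown mode {self.mode!r}")


def r2(panel: GenotypePanel, a: str, b: str) -> float:
    """Squared Pearson correlation between the dosage vectors of two variants."""
    return panel.r2_by_index(panel.index_of(a), panel.index_of(b))


def _join_panel(sumstats: SumStats, panel: GenotypePanel) -> pd.DataFrame:
    df = sumstats.df.copy()
    df["panel_idx"] = [
        panel._index.get(s, -1) for s in df["snp"]
    ]
    # monomorphic variants cannot be in LD with anything: treat like absent
    mono = panel.monomorphic
    df.loc[df["panel_idx"].map(lambda i: i >= 0 and bool(mono[i])), "panel_idx"] = -1
    return df


def prune(
    sumstats: SumStats,
    panel: GenotypePanel,
    cfg: PruneConfig = PruneConfig(),
    return_log: bool = False,
):
    """LD pruning, independent of p-value.

    Greedy left-to-right scan in (chrom, pos) order: a variant is kept unless
    its r² with an already-kept variant within ``bp_window`` reaches
    ``r2_max``.  Variants absent from (or monomorphic in) the panel pass
    through untouched.  Guarantees that no kept pair within the window has
    r² >= r2_max; re-pruning the output is a fixed point.
    """
    if cfg.mode != "pruning":
        raise ValueError("prune() requires cfg.mode == 'pruning'")
    df = _join_panel(sumstats, panel)
    keep = np.ones(len(df), dtype=bool)
    removals = []
    for chrom, sub in df.groupby("chrom", sort=False):
        kept: list[int] = []  # row positions (into df) of kept, panel-resident variants
        for row in sub.itertuples():
            i = row.Index
            if row.panel_idx < 0:
                continue  # pass-through, never compared
            drop_partner = None
            for j in reversed(kept):
                if row.pos - df.at[j, "pos"] > cfg.bp_window:
                    break
                rr = panel.r2_by_index(int(df.at[j, "panel_idx"]), int(row.panel_idx))
                if rr >= cfg.r2_max:
                    drop_partner = (df.at[j, "snp"], rr)
                    break
            if drop_partner is None:
                kept.append(i)
            else:
                keep[i] = False
                removals.append((row.snp, drop_partner[0], drop_partner[1]))
    out = SumStats(df.loc[keep, ["snp", "chrom", "pos", "p"]], sumstats.cohort_label)
    if return_log:
        log = pd.DataFrame(removals, columns=["snp", "partner", "r2"])
        return out, log
    return out


def clump(
    sumstats: SumStats,
    panel: GenotypePanel,
    cfg: PruneConfig = PruneConfig(mode="clumping"),
    return_log: bool = False,
):
    """LD clumping: keep the lead (smallest-p) signal of each LD block.

    Variants are visited in ascending p order (ties broken by chrom, pos,
    id); each unconsumed variant becomes a lead and consumes all unconsumed
    variants within ``bp_window`` whose r² with it reaches ``r2_max``.  The
    globally most significant variant is always kept.
    """
    if cfg.mode != "clumping":
        raise ValueError("clump() requires cfg.mode == 'clumping'")
    df = _join_panel(sumstats, panel)
    order = df.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort").index
    consumed = np.zeros(len(df), dtype=bool)
    is_lead = np.zeros(len(df), dtype=bool)
    removals = []
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pidx = df["panel_idx"].to_numpy()
    for i in order:
        if consumed[i]:
            continue
        is_lead[i] = True
        if pidx[i] < 0:
            continue  # pass-through lead of itself; cannot consume anything
        near = np.flatnonzero(
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= cfg.bp_window)
            & ~consumed
            & ~is_lead
            & (pidx >= 0)
        )
        for j in near:
            rr = panel.r2_by_index(int(pidx[i]), int(pidx[j]))
            if rr >= cfg.r2_max:
                consumed[j] = True
                removals.append((df.at[j, "snp"], df.at[i, "snp"], rr))
    out = SumStats(df.loc[is_lead, ["snp", "chrom", "pos", "p"]], sumstats.cohort_label)
    if return_log:
        log = pd.DataFrame(removals, columns=["snp", "lead", "r2"])
        return out, log
    return out


def apply_ld_filter(sumstats: SumStats, panel: GenotypePanel, cfg: PruneConfig) -> SumStats:
    """Dispatch to :func:`prune` or :func:`clump` according to ``cfg.mode``."""
    if cfg.mode == "pruning":
        return prune(sumstats, panel, cfg)
    return clump(sumstats, panel, cfg)
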