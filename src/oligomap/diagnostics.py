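"""Audit one annotation against another: cross-tables, bins, discrepancies.

Given two annotation tables over the same SNP set (typically the
manufacturer's and a fresh re-mapping), this module produces the summary
triple per source, 2x2 chromosome- and position-presence cross-tables, a
histogram of absolute position differences (0 / 1 / 2 / >=3 bases) for SNPs
placed on the same chromosome by both, and a per-SNP discrepancy class:

``chrom_one_side``
    a chromosome in exactly one source;
``chrom_conflict``
    chromosomes in both sources, but different ones;
``locus_one_side``
    same chromosome, a position in exactly one source;
``pos_gt2``
    same chromosome, positions in both, more than two bases apart;
``consistent``
    everything else (including SNPs unmapped by both sources).

The classes are assigned with exactly that precedence, each SNP gets one
label, and every non-``consistent`` label counts toward the substantial
total. Off-by-one and off-by-two position shifts are deliberately treated
as consistent: small systematic offsets reflect differing conventions for
which base a probe's position names, not a different locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

CHROM_ONE_SIDE = "chrom_one_side"
CHROM_CONFLICT = "chrom_conflict"
LOCUS_ONE_SIDE = "locus_one_side"
POS_GT2 = "pos_gt2"
CONSISTENT = "consistent"
CLASSES = (CHROM_ONE_SIDE, CHROM_CONFLICT, LOCUS_ONE_SIDE, POS_GT2, CONSISTENT)
SUBSTANTIAL_CLASSES = CLASSES[:4]

DIFF_BIN_LABELS = ("0", "1", "2", "3+")
_PRESENCE = ("absent", "present")
_CROSSTAB_CHROM = ("no_chromosome", "chromosome")
_CROSSTAB_POS = ("no_position", "position")


def _merge(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    ids_a, ids_b = set(a["ID"]), set(b["ID"])
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValidationError(
            f"annotation tables cover different SNP sets; symmetric difference"
            f" ({len(diff)} IDs): {diff[:10]}"
        )
    m = a.merge(b, on="ID", suffixes=(".A", ".B"), validate="one_to_one")
    return m


def _masks(m: pd.DataFrame):
    ca = m["CHROM.A"].notna().to_numpy()
    cb = m["CHROM.B"].notna().to_numpy()
    pa = m["POS.A"].notna().to_numpy()
    pb = m["POS.B"].notna().to_numpy()
    same_chrom = ca & cb & (m["CHROM.A"] == m["CHROM.B"]).fillna(False).to_numpy(dtype=bool)
    return ca, cb, pa, pb, same_chrom


def summarize_sources(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, tuple[int, int, int]]:
    """Per-source triple: (unique locus, chromosome only, neither)."""
    m = _merge(a, b)
    out = {}
    for key, chrom_col, pos_col in (("a", "CHROM.A", "POS.A"), ("b", "CHROM.B", "POS.B")):
        has_c = m[chrom_col].notna()
        has_p = m[pos_col].notna()
        out[key] = (
            int((has_c & has_p).sum()),
            int((has_c & ~has_p).sum()),
            int((~has_c).sum()),
        )
    return out


def _crosstab(mask_a: np.ndarray, mask_b: np.ndarray, labels: tuple[str, str]) -> pd.DataFrame:
    rows = np.where(mask_a, labels[1], labels[0])
    cols = np.where(mask_b, labels[1], labels[0])
    tab = pd.crosstab(pd.Series(rows, name="a"), pd.Series(cols, name="b"))
    return tab.reindex(index=list(labels), columns=list(labels), fill_value=0)


def crosstab_chromosome(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """2x2 chromosome-presence cross-table (rows: source a, cols: source b)."""
    m = _merge(a, b)
    ca, cb, _, _, _ = _masks(m)
    return _crosstab(ca, cb, _CROSSTAB_CHROM)


def crosstab_position(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """2x2 position-presence cross-table over SNPs with a chromosome in both."""
    m = _merge(a, b)
    ca, cb, pa, pb, _ = _masks(m)
    both = ca & cb
    return _crosstab(pa[both], pb[both], _CROSSTAB_POS)


def bin_position_differences(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[dict[str, int], pd.DataFrame]:
    """Histogram |pos_a - pos_b| into 0/1/2/>=3 for same-chromosome SNPs.

    Only SNPs with the same chromosome in both sources and a position in
    both are binned; chromosome conflicts are routed to the discrepancy
    classes instead. Also returns the per-SNP differences.
    """
    m = _merge(a, b)
    _, _, pa, pb, same_chrom = _masks(m)
    mask = same_chrom & pa & pb
    sub = m.loc[mask]
    delta = (sub["POS.A"].astype("int64") - sub["POS.B"].astype("int64")).abs()
    bins = {
        "0": int((delta == 0).sum()),
        "1": int((delta == 1).sum()),
        "2": int((delta == 2).sum()),
        "3+": int((delta >= 3).sum()),
    }
    detail = pd.DataFrame({"ID": sub["ID"].to_numpy(), "DELTA": delta.to_numpy()})
    return bins, detail


def classify_discrepancies(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Assign each SNP one discrepancy class; count non-consistent SNPs.

    Returns a Series of labels indexed by SNP ID and the substantial total.
    """
    m = _merge(a, b)
    ca, cb, pa, pb, same_chrom = _masks(m)
    delta_gt2 = np.zeros(len(m), dtype=bool)
    both_pos = same_chrom & pa & pb
    if both_pos.any():
        d = (
            m.loc[both_pos, "POS.A"].astype("int64")
            - m.loc[both_pos, "POS.B"].astype("int64")
        ).abs()
        delta_gt2[np.flatnonzero(both_pos)] = (d > 2).to_numpy()
    conditions = [
        ca ^ cb,
        ca & cb & ~same_chrom,
        same_chrom & (pa ^ pb),
        delta_gt2,
    ]
    labels = np.select(conditions, SUBSTANTIAL_CLASSES, default=CONSISTENT)
    series = pd.Series(labels, index=pd.Index(m["ID"], name="ID"), name="CLASS")
    return series, int((labels != CONSISTENT).sum())


@dataclass
class DiscrepancyReport:
    """Bundle of every comparison the audit produces for two sources."""

    n: int
    summary_counts: dict[str, tuple[int, int, int]]
    chrom_crosstab: pd.DataFrame
    pos_crosstab: pd.DataFrame
    diff_bins: dict[str, int]
    diff_detail: pd.DataFrame
    classes: pd.Series
    substantial_total: int

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.classes.value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def to_text(self) -> str:
        """Human-readable report with the three tables and the class tally."""
        lines = [f"SNPs compared: {self.n}", ""]
        lines.append("Mapped to (unique locus / chromosome only / neither):")
        for key, triple in self.summary_counts.items():
            pct = " / ".join(f"{100.0 * v / self.n:.1f}%" for v in triple) if self.n else ""
            lines.append(f"  source {key}: {triple}  ({pct})")
        lines.append("")
        lines.append("Chromosome assignment cross-table (rows: a, cols: b):")
        lines.append(self.chrom_crosstab.to_string())
        lines.append("")
        lines.append("Position assignment cross-table (chromosome in both):")
        lines.append(self.pos_crosstab.to_string())
        lines.append("")
        lines.append("Absolute position differences (same chromosome, both placed):")
        lines.append("  " + "  ".join(f"|d|={k}: {v}" for k, v in self.diff_bins.items()))
        lines.append("")
        lines.append("Discrepancy classes:")
        for cls, cnt in self.class_counts.items():
            lines.append(f"  {cls}: {cnt}")
        lines.append(f"Substantial discrepancies: {self.substantial_total}")
        return "\n".join(lines)


def compare_annotations(a: pd.DataFrame, b: pd.DataFrame) -> DiscrepancyReport:
    """Run the full audit of source ``a`` against source ``b``."""
    classes, substantial = classify_discrepancies(a, b)
    bins, detail = bin_position_differences(a, b)
    return DiscrepancyReport(
        n=len(a),
        summary_counts=summarize_sources(a, b),
        chrom_crosstab=crosstab_chromosome(a, b),
        pos_crosstab=crosstab_position(a, b),
        diff_bins=bins,
        diff_detail=detail,
        classes=classes,
        substantial_total=substantial,
    )
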