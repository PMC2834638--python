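"""Seeded synthetic fixtures: toy genome, probes with planted fates, truth.

The generator emulates the inputs of a probe re-mapping study at desk
scale: a genome of a few placed chromosomes plus unplaced scaffolds
(i.i.d. uniform ACGT), a manifest of fixed-length probes, and a
"manufacturer" annotation derived from the truth by controlled
perturbation. Every probe is planted with a declared *fate* that forces a
specific branch of the locus-assignment decision tree:

``unique_plus`` / ``unique_minus``
    copied verbatim from (or as reverse complement of) one genomic window;
``dup_same_chrom`` / ``dup_cross_chrom``
    the same oligomer written at two loci on one / on two chromosomes;
``unplaced_only``
    planted only on an unplaced scaffold (filtered out downstream);
``absent``
    a random oligomer verified by scanning to occur nowhere;
``mismatched_<k>``
    a planted copy with k interior probe bases mutated — recoverable while
    the full-length identity stays above the threshold, otherwise hit-less;
``duplicate_id_pair`` / ``revcomp_pair``
    two manifest records sharing one sequence (or its reverse complement).

Plantings are non-overlapping and at least a probe length apart, so the
expected hit set of each probe is unambiguous and the generator can state
the exact expected locus call (the truth record) for every probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dg
from .aligner import Genome, scan_oligos
from .duplicates import DuplicatePair, IDENTICAL, REVCOMP, reverse_complement
from .errors import GenerationError
from .locus import CHROM_ONLY, CROSS_CHROM_TIE, NO_HIT, UNIQUE
from .manifest_io import OligoRecord, annotation_table

UNIQUE_PLUS = "unique_plus"
UNIQUE_MINUS = "unique_minus"
DUP_SAME_CHROM = "dup_same_chrom"
DUP_CROSS_CHROM = "dup_cross_chrom"
UNPLACED_ONLY = "unplaced_only"
ABSENT = "absent"
DUP_ID_PAIR = "duplicate_id_pair"
REVCOMP_PAIR = "revcomp_pair"
OFF_BY_ONE = "off_by_one"

#: Default planted fates: 1,000 probes dominated by cleanly mappable ones,
#: with every decision-tree branch represented.
DEFAULT_FATE_COUNTS: dict[str, int] = {
    UNIQUE_PLUS: 700,
    UNIQUE_MINUS: 100,
    DUP_SAME_CHROM: 60,
    DUP_CROSS_CHROM: 40,
    UNPLACED_ONLY: 30,
    ABSENT: 40,
    "mismatched_1": 20,
    "mismatched_3": 10,
}

#: Default annotation perturbation: a handful of each substantial class plus
#: a block of off-by-one shifts mimicking the dominant benign disagreement
#: between mapping conventions.
DEFAULT_PERTURBATION_COUNTS: dict[str, int] = {
    dg.CHROM_ONE_SIDE: 3,
    dg.CHROM_CONFLICT: 2,
    dg.LOCUS_ONE_SIDE: 4,
    dg.POS_GT2: 5,
    OFF_BY_ONE: 20,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def mismatched_fate(k: int) -> str:
    return f"mismatched_{k}"


def _mismatch_k(fate: str) -> int | None:
    if fate.startswith("mismatched_"):
        return int(fate.split("_", 1)[1])
    return None


@dataclass
class FixtureSpec:
    """Everything needed to generate one reproducible fixture."""

    n_chromosomes: int = 3
    chrom_length: int = 200_000
    n_unplaced: int = 5
    unplaced_length: int = 20_000
    probe_length: int = 50
    min_identity: float = 95.0
    fate_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FATE_COUNTS)
    )
    perturbation_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PERTURBATION_COUNTS)
    )
    seed: int = 0

    @property
    def manifest_size(self) -> int:
        """Total records: pair fates contribute two records per planted pair."""
        n = 0
        for fate, count in self.fate_counts.items():
            n += 2 * count if fate in (DUP_ID_PAIR, REVCOMP_PAIR) else count
        return n


@dataclass(frozen=True)
class TruthRecord:
    """The generator's planted fate and expected locus call for one probe."""

    snp_id: str
    fate: str
    expected_chromosome: str | None
    expected_position: int | None
    expected_status: str
    partner_id: str | None = None  # other member of a planted duplicate pair


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def generate_genome(spec: FixtureSpec) -> Genome:
    """I.i.d. uniform-ACGT genome; placed chromosomes "1".. plus scaffolds."""
    if spec.chrom_length < 10 * spec.probe_length or (
        spec.n_unplaced and spec.unplaced_length < 10 * spec.probe_length
    ):
        raise GenerationError("sequences must be at least 10 probe lengths long")
    rng = np.random.default_rng([spec.seed, 0])
    sequences: dict[str, str] = {}
    for i in range(spec.n_chromosomes):
        sequences[str(i + 1)] = _random_dna(rng, spec.chrom_length)
    for i in range(spec.n_unplaced):
        sequences[f"ChrUn_scaffold_{i + 1}"] = _random_dna(rng, spec.unplaced_length)
    whitelist = frozenset(str(i + 1) for i in range(spec.n_chromosomes))
    return Genome(sequences=sequences, whitelist=whitelist)


def _slot_starts(length: int, L: int) -> list[int]:
    # non-overlapping windows >= L apart, keeping a margin of L at both ends
    return list(range(L, length - 2 * L, 2 * L))


def plant_probes(
    genome: Genome, spec: FixtureSpec
) -> tuple[list[OligoRecord], list[TruthRecord], Genome]:
    """Plant every requested fate; return probes, truth and mutated genome.

    Duplicate-locus fates write copies of an oligomer into the genome, so
    the returned genome replaces the input one downstream. The manifest
    order is shuffled (seeded) so fates are not positionally encoded.
    """
    rng = np.random.default_rng([spec.seed, 1])
    L = spec.probe_length
    placed = sorted(genome.whitelist, key=lambda s: (len(s), s))
    unplaced = [lab for lab in genome.sequences if lab not in genome.whitelist]
    seqs = {lab: bytearray(s, "ascii") for lab, s in genome.sequences.items()}

    pools: dict[str, list[int]] = {}
    for lab, s in genome.sequences.items():
        starts = _slot_starts(len(s), L)
        pools[lab] = [int(x) for x in rng.permutation(starts)]

    def take(lab: str) -> int:
        if not pools[lab]:
            raise GenerationError(f"no free planting slot left on {lab!r}")
        return pools[lab].pop()

    counts = dict(spec.fate_counts)
    plan: list[dict] = []
    pair_tag = 0

    def window(lab: str, q: int) -> str:
        return seqs[lab][q : q + L].decode("ascii")

    # fates needing two same- or cross-chromosome loci first (they also
    # mutate the genome)
    for i in range(counts.get(DUP_SAME_CHROM, 0)):
        if not placed:
            raise GenerationError("dup_same_chrom requires a placed chromosome")
        lab = placed[i % len(placed)]
        q1, q2 = take(lab), take(lab)
        seqs[lab][q2 : q2 + L] = seqs[lab][q1 : q1 + L]
        plan.append(
            dict(fate=DUP_SAME_CHROM, seq=None, src=(lab, q1),
                 chrom=lab, pos=None, status=CHROM_ONLY)
        )
    for i in range(counts.get(DUP_CROSS_CHROM, 0)):
        if len(placed) < 2:
            raise GenerationError("dup_cross_chrom requires >= 2 chromosomes")
        lab1 = placed[i % len(placed)]
        lab2 = placed[(i + 1) % len(placed)]
        q1, q2 = take(lab1), take(lab2)
        seqs[lab2][q2 : q2 + L] = seqs[lab1][q1 : q1 + L]
        plan.append(
            dict(fate=DUP_CROSS_CHROM, seq=None, src=(lab1, q1),
                 chrom=None, pos=None, status=CROSS_CHROM_TIE)
        )

    # single-locus placed fates
    flat_placed: list[tuple[str, int]] = []
    for lab in placed:
        flat_placed.extend((lab, q) for q in pools[lab])
    order = rng.permutation(len(flat_placed))
    flat_iter = iter([flat_placed[int(i)] for i in order])

    def next_placed() -> tuple[str, int]:
        try:
            return next(flat_iter)
        except StopIteration:
            raise GenerationError("ran out of placed planting slots") from None

    for _ in range(counts.get(UNIQUE_PLUS, 0)):
        lab, q = next_placed()
        plan.append(
            dict(fate=UNIQUE_PLUS, seq=None, src=(lab, q),
                 chrom=lab, pos=q + L + 1, status=UNIQUE)
        )
    for _ in range(counts.get(UNIQUE_MINUS, 0)):
        lab, q = next_placed()
        plan.append(
            dict(fate=UNIQUE_MINUS, seq=None, src=(lab, q), revcomp=True,
                 chrom=lab, pos=q, status=UNIQUE)
        )
    for fate, count in sorted(counts.items()):
        k = _mismatch_k(fate)
        if k is None:
            continue
        if not 1 <= k <= L - 2:
            raise GenerationError(f"mismatch count {k} out of range for L={L}")
        recover = (L - k) * 100.0 >= spec.min_identity * L - 1e-9
        for _ in range(count):
            lab, q = next_placed()
            plan.append(
                dict(fate=fate, seq=None, src=(lab, q), mutate=k,
                     chrom=lab if recover else None,
                     pos=q + L + 1 if recover else None,
                     status=UNIQUE if recover else NO_HIT)
            )
    for _ in range(counts.get(DUP_ID_PAIR, 0)):
        lab, q = next_placed()
        for member in (0, 1):
            plan.append(
                dict(fate=DUP_ID_PAIR, seq=None, src=(lab, q),
                     chrom=lab, pos=q + L + 1, status=UNIQUE, tag=pair_tag)
            )
        pair_tag += 1
    for _ in range(counts.get(REVCOMP_PAIR, 0)):
        lab, q = next_placed()
        plan.append(
            dict(fate=REVCOMP_PAIR, seq=None, src=(lab, q),
                 chrom=lab, pos=q + L + 1, status=UNIQUE, tag=pair_tag)
        )
        plan.append(
            dict(fate=REVCOMP_PAIR, seq=None, src=(lab, q), revcomp=True,
                 chrom=lab, pos=q, status=UNIQUE, tag=pair_tag)
        )
        pair_tag += 1

    # unplaced-scaffold plantings
    flat_un: list[tuple[str, int]] = []
    for lab in unplaced:
        flat_un.extend((lab, q) for q in pools[lab])
    if counts.get(UNPLACED_ONLY, 0) > len(flat_un):
        raise GenerationError("not enough unplaced-scaffold slots")
    order = rng.permutation(len(flat_un))
    un_iter = iter([flat_un[int(i)] for i in order])
    for _ in range(counts.get(UNPLACED_ONLY, 0)):
        lab, q = next(un_iter)
        plan.append(
            dict(fate=UNPLACED_ONLY, seq=None, src=(lab, q),
                 chrom=None, pos=None, status=NO_HIT)
        )

    # all genome writes are done: read planted sequences
    for entry in plan:
        lab, q = entry["src"]
        s = window(lab, q)
        if entry.get("mutate"):
            s = _mutate(rng, s, entry["mutate"])
        if entry.get("revcomp"):
            s = reverse_complement(s)
        entry["seq"] = s

    final_sequences = {lab: bytes(b).decode("ascii") for lab, b in seqs.items()}
    mutated = Genome(sequences=final_sequences, whitelist=genome.whitelist)

    # absent probes, verified to have no hit anywhere at the fixture's
    # identity threshold
    n_absent = counts.get(ABSENT, 0)
    candidates = [_random_dna(rng, L) for _ in range(n_absent)]
    for _ in range(10):
        probes = [
            OligoRecord(oligo_id=f"cand{i}", sequence=s)
            for i, s in enumerate(candidates)
        ]
        hit_ids = {
            h.query_id for h in scan_oligos(mutated, probes, spec.min_identity)
        }
        if not hit_ids:
            break
        candidates = [
            _random_dna(rng, L) if f"cand{i}" in hit_ids else s
            for i, s in enumerate(candidates)
        ]
    else:
        raise GenerationError("could not generate hit-free absent probes")
    for s in candidates:
        plan.append(dict(fate=ABSENT, seq=s, chrom=None, pos=None, status=NO_HIT))

    # shuffle manifest order, then assign identifiers
    order = rng.permutation(len(plan))
    plan = [plan[int(i)] for i in order]
    width = max(5, len(str(len(plan))))
    records: list[OligoRecord] = []
    tag_ids: dict[int, list[str]] = {}
    for i, entry in enumerate(plan):
        snp_id = f"S{i:0{width}d}"
        entry["snp_id"] = snp_id
        if "tag" in entry:
            tag_ids.setdefault(entry["tag"], []).append(snp_id)
        seq = entry["seq"]
        a = seq[0]
        b = rng.choice([x for x in "ACGT" if x != a])
        records.append(
            OligoRecord(
                oligo_id=snp_id,
                sequence=seq,
                ilmn_strand="BOT" if entry.get("revcomp") else "TOP",
                source_strand="TOP",
                alleles=f"[{a}/{b}]",
            )
        )
    truths = [
        TruthRecord(
            snp_id=entry["snp_id"],
            fate=entry["fate"],
            expected_chromosome=entry["chrom"],
            expected_position=entry["pos"],
            expected_status=entry["status"],
            partner_id=_partner(tag_ids, entry),
        )
        for entry in plan
    ]
    return records, truths, mutated


def _partner(tag_ids: dict[int, list[str]], entry: dict) -> str | None:
    if "tag" not in entry:
        return None
    a, b = tag_ids[entry["tag"]]
    return b if entry["snp_id"] == a else a


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Mutate k distinct interior bases (never the terminal ones)."""
    positions = rng.choice(np.arange(1, len(seq) - 1), size=k, replace=False)
    chars = list(seq)
    for p in positions:
        chars[int(p)] = str(rng.choice([x for x in "ACGT" if x != chars[int(p)]]))
    return "".join(chars)


def truth_annotation(truths: list[TruthRecord]) -> pd.DataFrame:
    """Annotation table of the expected chromosome/position per probe."""
    return annotation_table(
        (t.snp_id, t.expected_chromosome, t.expected_position) for t in truths
    )


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ID": [t.snp_id for t in truths],
            "FATE": [t.fate for t in truths],
            "CHROM": [t.expected_chromosome for t in truths],
            "POS": pd.array([t.expected_position for t in truths], dtype="Int64"),
            "STATUS": [t.expected_status for t in truths],
            "PARTNER": [t.partner_id for t in truths],
        }
    )


def planted_pairs(truths: list[TruthRecord]) -> list[DuplicatePair]:
    """The duplicate pairs the generator planted, as ground truth."""
    pairs = set()
    for t in truths:
        if t.partner_id is None:
            continue
        kind = IDENTICAL if t.fate == DUP_ID_PAIR else REVCOMP
        pairs.add(DuplicatePair(min(t.snp_id, t.partner_id),
                                max(t.snp_id, t.partner_id), kind))
    return sorted(pairs)


def perturb_annotation(
    table: pd.DataFrame, spec: FixtureSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the requested discrepancy classes to disjoint row sets.

    Rows with both chromosome and position are eligible. Returns the
    perturbed copy and a ledger DataFrame (ID, PLANTED) naming the class
    planted on each touched row; off-by-one shifts are planted as benign
    (they classify as consistent downstream).
    """
    rng = np.random.default_rng([spec.seed if seed is None else seed, 2])
    out = table.copy(deep=True)
    eligible = np.flatnonzero(out["CHROM"].notna() & out["POS"].notna())
    wanted = {k: int(v) for k, v in spec.perturbation_counts.items() if v}
    need = sum(wanted.values())
    if need > len(eligible):
        raise GenerationError(
            f"perturbation needs {need} fully mapped rows, only {len(eligible)}"
            " available"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    labels = sorted(out["CHROM"].dropna().unique().tolist())
    ledger_rows: list[tuple[str, str]] = []
    cursor = 0
    order = (dg.CHROM_ONE_SIDE, dg.CHROM_CONFLICT, dg.LOCUS_ONE_SIDE,
             dg.POS_GT2, OFF_BY_ONE)
    for cls in order:
        count = wanted.get(cls, 0)
        for idx in chosen[cursor : cursor + count]:
            idx = int(idx)
            row_id = out.at[idx, "ID"]
            if cls == dg.CHROM_ONE_SIDE:
                out.at[idx, "CHROM"] = pd.NA
                out.at[idx, "POS"] = pd.NA
            elif cls == dg.CHROM_CONFLICT:
                if len(labels) < 2:
                    raise GenerationError(
                        "chrom_conflict perturbation needs >= 2 chromosomes"
                    )
                cur = out.at[idx, "CHROM"]
                out.at[idx, "CHROM"] = labels[(labels.index(cur) + 1) % len(labels)]
            elif cls == dg.LOCUS_ONE_SIDE:
                out.at[idx, "POS"] = pd.NA
            elif cls == dg.POS_GT2:
                d = int(rng.integers(3, 11))
                sign = -1 if rng.integers(0, 2) and out.at[idx, "POS"] - d >= 1 else 1
                out.at[idx, "POS"] = out.at[idx, "POS"] + sign * d
            else:  # off-by-one
                sign = -1 if rng.integers(0, 2) and out.at[idx, "POS"] > 1 else 1
                out.at[idx, "POS"] = out.at[idx, "POS"] + sign
            ledger_rows.append((row_id, cls))
        cursor += count
    ledger = pd.DataFrame(ledger_rows, columns=["ID", "PLANTED"])
    return out, ledger


# ---------------------------------------------------------------------------
# fixture directory writer

_MANIFEST_HEAD = [
    "[Heading]",
    "Descriptor File Name,oligomap synthetic fixture",
    "Assay Format,synthetic",
    "Date Manufactured,NA",
    "Loci Count,{n}",
    "",
    "[Assay]",
]


def write_fixture(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Generate a full fixture and write it as plain-text files.

    Produces genome FASTA, a manufacturer-style manifest CSV (with metadata
    head and control footer lines), the truth table, the truth-derived
    annotation and its perturbed "manufacturer" counterpart, and the
    perturbation ledger.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(spec)
    records, truths, genome = plant_probes(genome, spec)
    truth_ann = truth_annotation(truths)
    perturbed, ledger = perturb_annotation(truth_ann, spec)

    paths = {
        "genome": outdir / "genome.fasta",
        "manifest": outdir / "manifest.csv",
        "truth": outdir / "truth.csv",
        "annotation_truth": outdir / "annotation.map.csv",
        "annotation_vendor": outdir / "annotation.vendor.csv",
        "ledger": outdir / "perturbation_ledger.csv",
    }
    genome.to_fasta(paths["genome"])
    _write_manifest(records, paths["manifest"])
    truth_frame(truths).to_csv(paths["truth"], index=False, na_rep="NA")
    truth_ann.to_csv(paths["annotation_truth"], index=False, na_rep="NA")
    perturbed.to_csv(paths["annotation_vendor"], index=False, na_rep="NA")
    ledger.to_csv(paths["ledger"], index=False)
    return paths


def _write_manifest(records: list[OligoRecord], path) -> None:
    df = pd.DataFrame(
        {
            "Name": [r.oligo_id for r in records],
            "IlmnStrand": [r.ilmn_strand for r in records],
            "SourceStrand": [r.source_strand for r in records],
            "SNP": [r.alleles for r in records],
            "AlleleA_ProbeSeq": [r.sequence for r in records],
        }
    )
    with open(path, "w") as fh:
        for line in _MANIFEST_HEAD:
            fh.write(line.format(n=len(records)) + "\n")
        df.to_csv(fh, index=False)
        fh.write("[Controls]\n")
        for i in range(52):
            fh.write(f"CTRL{i:02d},synthetic control\n")
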