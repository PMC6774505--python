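"""Seeded synthetic genomes with implanted prophage-like islands.

The generator produces exactly the inputs the pipeline consumes — genome
FASTA, GFF3 annotation, 12-column hit table, truth BED — with the
statistical structure the detector assumes: background genes at bacterial
spacing (~1 gene/kb) with at most weak similarity to phage proteins, and
dense islands of genes carrying strong phage hits, optionally flanked by
tRNA genes at known offsets. Everything is deterministic given the seed.

E-values for phage-like genes are drawn log-uniform in [1e-50, 1e-6] and
for background noise in [1e-4, 10]; the gap straddles the 1e-5 decision
cutoff so threshold behaviour is exercised from both sides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .edge_refine import DEFAULT_TRNA_FLANK
from .intervals import Interval
from .io_formats import (
    ContigSeq,
    GeneFeature,
    write_bed,
    write_fasta,
    write_gff3,
)

TRNA_LEN = 75

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class ScenarioError(ValueError):
    """The scenario violates its own constraints (e.g. overlapping islands)."""


@dataclass(frozen=True)
class Island:
    """A block of densely packed genes destined to carry phage hits.

    ``left_trna``/``right_trna`` give the gap in bp between the island's
    outermost gene boundary and the near edge of an optional flanking tRNA
    gene; ``None`` places no tRNA on that side.
    """

    position: int
    n_genes: int = 12
    gene_len: int = 900
    spacing: int = 100
    phage_fraction: float = 1.0
    left_trna: Optional[int] = None
    right_trna: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_len < 6 or self.gene_len % 3:
            raise ScenarioError(
                f"island at {self.position}: gene_len must be a positive multiple of 3"
            )
        if not 0.0 <= self.phage_fraction <= 1.0:
            raise ScenarioError(f"phage_fraction {self.phage_fraction} outside [0, 1]")

    @property
    def gene_span(self) -> tuple[int, int]:
        """[start, end) of the gene block itself."""
        end = self.position + self.n_genes * self.gene_len + (self.n_genes - 1) * self.spacing
        return self.position, end

    @property
    def footprint(self) -> tuple[int, int]:
        """[start, end) including any flanking tRNAs."""
        s, e = self.gene_span
        if self.left_trna is not None:
            s -= self.left_trna + TRNA_LEN
        if self.right_trna is not None:
            e += self.right_trna + TRNA_LEN
        return s, e


@dataclass(frozen=True)
class SimScenario:
    """Full description of one synthetic contig.

    ``gene_density`` is background genes per kb (bacterial genomes run
    close to 1 coding gene per kb); ``background_phage_rate`` is the
    probability that a background gene receives a *strong* (phage-grade)
    hit, and ``background_hit_rate`` the probability of a weak hit above
    the cutoff. Decoy positions carry isolated genes with very strong hits
    (e-value 1e-30) — sub-threshold signal the detector must ignore.
    """

    seed: int = 0
    contig_id: str = "contig_1"
    contig_len: int = 100_000
    gene_density: float = 0.9
    background_phage_rate: float = 0.0
    background_hit_rate: float = 0.2
    islands: tuple[Island, ...] = ()
    decoy_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "islands", tuple(self.islands))
        object.__setattr__(self, "decoy_positions", tuple(self.decoy_positions))
        spans = sorted(i.footprint for i in self.islands)
        for (s, e), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e:
                raise ScenarioError(f"islands overlap: [{s},{e}) and [{s2},{e2})")
        for s, e in spans:
            if s < 0 or e > self.contig_len:
                raise ScenarioError(
                    f"island footprint [{s},{e}) outside contig of length {self.contig_len}"
                )


@dataclass
class SyntheticDataset:
    """In-memory fixture set: genome, annotation, hit rows, truth intervals."""

    contigs: list[ContigSeq]
    features: list[GeneFeature]
    hit_rows: list[tuple[str, ...]]
    truth: list[Interval]
    phage_gene_ids: set[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genome.fna, annotation.gff3, hits.tsv and truth.bed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fna",
            "gff": outdir / "annotation.gff3",
            "hits": outdir / "hits.tsv",
            "truth": outdir / "truth.bed",
        }
        write_fasta(((c.contig_id, c.sequence) for c in self.contigs), paths["fasta"])
        write_gff3(self.features, self.contigs, paths["gff"])
        with open(paths["hits"], "w") as fh:
            for row in self.hit_rows:
                fh.write("\t".join(row) + "\n")
        write_bed(self.truth, paths["truth"])
        return paths


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """ATG + random sense codons + TAA, exactly ``length`` nt."""
    n_mid = length // 3 - 2
    mid = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_mid)
    )
    return "ATG" + mid + "TAA"


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate(scenario: SimScenario) -> SyntheticDataset:
    """Generate the full fixture set for one scenario.

    Background genes are laid down left to right at the scenario's density,
    skipping island footprints and decoy slots; island genes and decoys are
    placed exactly where the scenario says. Gene bodies in the contig
    sequence are well-formed CDSs (forced start/stop, no internal stop) so
    translation round-trips cleanly. The truth BED spans each island's
    genes, extended to a flanking tRNA's outward coordinate whenever that
    tRNA lies within the edge-refinement search range of the island border.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.contig_len

    # (start, end, strand, kind, island_index) — kind in {background, island, decoy}
    gene_slots: list[tuple[int, int, str, str, int]] = []
    reserved: list[tuple[int, int]] = []

    for idx, isl in enumerate(scenario.islands):
        pos = isl.position
        for g in range(isl.n_genes):
            s = pos + g * (isl.gene_len + isl.spacing)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_slots.append((s, s + isl.gene_len, strand, "island", idx))
        reserved.append(isl.footprint)

    decoy_len = 900
    for pos in scenario.decoy_positions:
        s = max(0, min(pos, L - decoy_len))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_slots.append((s, s + decoy_len, strand, "decoy", -1))
        reserved.append((s, s + decoy_len))

    reserved.sort()
    pitch = max(300, int(round(1000 / scenario.gene_density)))
    cursor = int(rng.integers(0, 200))
    while True:
        glen = int(rng.integers(200, 401)) * 3  # 600-1200 nt, whole codons
        gap = int(rng.integers(max(30, pitch - glen - 200), max(60, pitch - glen + 200)))
        s = cursor + gap
        e = s + glen
        if e > L:
            break
        clash = next((r for r in reserved if s < r[1] + 100 and r[0] - 100 < e), None)
        if clash is not None:
            cursor = clash[1] + 100
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene_slots.append((s, e, strand, "background", -1))
        cursor = e

    gene_slots.sort(key=lambda t: t[0])

    # contig sequence: random background, gene bodies overwritten with real CDSs
    seq = bytearray(_BASES[rng.integers(0, 4, L)].tobytes())
    features: list[GeneFeature] = []
    kinds: list[tuple[str, str, int]] = []  # (gene_id, kind, island_index)
    for i, (s, e, strand, kind, idx) in enumerate(gene_slots, 1):
        gid = f"g{i:05d}"
        body = _coding_seq(rng, e - s)
        if strand == "-":
            body = _revcomp(body)
        seq[s:e] = body.encode()
        features.append(
            GeneFeature(gid, scenario.contig_id, s, e, strand, "CDS", "hypothetical protein", 0)
        )
        kinds.append((gid, kind, idx))

    # flanking tRNAs
    trna_by_island: dict[tuple[int, str], GeneFeature] = {}
    for idx, isl in enumerate(scenario.islands):
        gs, ge = isl.gene_span
        if isl.left_trna is not None:
            t_end = gs - isl.left_trna
            f = GeneFeature(
                f"trna_{idx + 1}_left", scenario.contig_id, t_end - TRNA_LEN, t_end,
                "+", "tRNA", "tRNA-Synthetic",
            )
            features.append(f)
            trna_by_island[(idx, "left")] = f
        if isl.right_trna is not None:
            t_start = ge + isl.right_trna
            f = GeneFeature(
                f"trna_{idx + 1}_right", scenario.contig_id, t_start, t_start + TRNA_LEN,
                "+", "tRNA", "tRNA-Synthetic",
            )
            features.append(f)
            trna_by_island[(idx, "right")] = f
    features.sort(key=lambda f: (f.start, f.end))

    # similarity hits
    hit_rows: list[tuple[str, ...]] = []
    phage_ids: set[str] = set()
    feat_by_id = {f.feature_id: f for f in features}
    for gid, kind, idx in kinds:
        feat = feat_by_id[gid]
        aa_len = (feat.end - feat.start) // 3 - 1
        if kind == "decoy":
            hit_rows.append(_hit_row(rng, gid, aa_len, evalue=1e-30))
            phage_ids.add(gid)
        elif kind == "island":
            if rng.random() < scenario.islands[idx].phage_fraction:
                hit_rows.append(_hit_row(rng, gid, aa_len, strong=True))
                phage_ids.add(gid)
        else:  # background
            if rng.random() < scenario.background_phage_rate:
                hit_rows.append(_hit_row(rng, gid, aa_len, strong=True))
                phage_ids.add(gid)
            elif rng.random() < scenario.background_hit_rate:
                hit_rows.append(_hit_row(rng, gid, aa_len, strong=False))

    # truth intervals: island gene span, extended to tRNAs the refiner will see
    truth: list[Interval] = []
    for idx, isl in enumerate(scenario.islands):
        gs, ge = isl.gene_span
        s, e = gs, ge
        left = trna_by_island.get((idx, "left"))
        if left is not None and left.start < gs + DEFAULT_TRNA_FLANK and left.end > gs - DEFAULT_TRNA_FLANK:
            s = left.start
        right = trna_by_island.get((idx, "right"))
        if right is not None and right.start < ge + DEFAULT_TRNA_FLANK and right.end > ge - DEFAULT_TRNA_FLANK:
            e = right.end
        if any(k == "island" and i == idx and g in phage_ids for g, k, i in kinds):
            truth.append(Interval(scenario.contig_id, s, e))

    contig = ContigSeq(scenario.contig_id, seq.decode())
    return SyntheticDataset([contig], features, hit_rows, truth, phage_ids)


def _hit_row(
    rng: np.random.Generator,
    gene_id: str,
    aa_len: int,
    strong: bool = True,
    evalue: Optional[float] = None,
) -> tuple[str, ...]:
    """One plausible 12-column tabular alignment row."""
    if evalue is None:
        evalue = 10.0 ** rng.uniform(-50, -6) if strong else 10.0 ** rng.uniform(-4, 1)
    subject = f"PHG{rng.integers(1, 500):04d}_p{rng.integers(1, 100):03d}"
    pident = round(float(rng.uniform(30, 95)), 1)
    length = max(20, aa_len)
    mismatch = int(round(length * (100 - pident) / 100))
    bitscore = round(max(25.0, 400.0 + 15.0 * np.log10(max(evalue, 1e-180))), 1)
    return (
        gene_id, subject, f"{pident:.1f}", str(length), str(mismatch), "0",
        "1", str(length), "1", str(length), f"{evalue:.2e}", f"{bitscore:.1f}",
    )


def decoy_inject(scenario: SimScenario, n_decoys: int, min_separation: int = 15_000) -> SimScenario:
    """Return a scenario with ``n_decoys`` isolated strong-hit genes added.

    Decoys are spread deterministically across free space, at least
    ``min_separation`` bp from islands, existing decoys and each other, so
    no window can accumulate enough of them to cross the gene threshold.
    """
    forbidden = [i.footprint for i in scenario.islands] + [
        (p, p + 900) for p in scenario.decoy_positions
    ]
    positions: list[int] = list(scenario.decoy_positions)
    new: list[int] = []
    step = max(1000, scenario.contig_len // (4 * max(1, n_decoys)))
    pos = min_separation // 2
    while len(new) < n_decoys and pos + 900 < scenario.contig_len:
        ok = all(
            pos + 900 + min_separation <= s or e + min_separation <= pos
            for s, e in forbidden
        ) and all(abs(pos - q) >= min_separation for q in positions + new)
        if ok:
            new.append(pos)
            pos += min_separation
        else:
            pos += step
    if len(new) < n_decoys:
        raise ScenarioError(
            f"could not place {n_decoys} decoys {min_separation} bp apart in a "
            f"{scenario.contig_len} bp contig"
        )
    return dataclasses.replace(scenario, decoy_positions=tuple(positions + new))


def scenario_from_dict(config: dict) -> SimScenario:
    """Build a scenario from a plain dict (e.g. parsed JSON config)."""
    cfg = dict(config)
    islands = tuple(Island(**d) for d in cfg.pop("islands", ()))
    return SimScenario(islands=islands, **cfg)
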