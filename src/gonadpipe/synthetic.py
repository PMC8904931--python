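"""Ground-truth-annotated synthetic gonad reads and peptide detections.

The generator emulates the statistical structure the pipeline assumes,
so every downstream stage can be exercised without external data:

* a pool of genes, each with a random coding sequence (ATG ... stop)
  embedded between random non-coding flanks on a longer stranded
  transcript;
* log-scale tissue-biased abundance — per-gene log10-TPM drawn
  Normal(mean_log_tpm, sd_log_tpm), with biased genes shifted by
  ``bias_log10_fold`` (> 1, i.e. more than 10-fold) in one tissue;
* two tissues x two biological replicates, read counts per sample drawn
  multinomially from the tissue abundances; reads are error-free copies
  of their transcript (an optional substitution rate supports clustering
  stress tests);
* peptide detection tables drawn from the in-silico digest of database
  proteins, each filter-passing peptide retained with probability
  ``detection_prob`` and given a log-normal intensity.

Flanks are rejection-sampled until the greedy non-overlapping ORF
selection on the whole transcript returns exactly the embedded coding
sequence, so the ground-truth ORF is the unique expected call.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import SampleLabel
from .digest import enumerate_ions
from .io import write_fasta, write_tsv
from .orfs import MIN_PROTEIN_LENGTH, find_orfs, select_nonoverlapping

logger = logging.getLogger(__name__)

_SENSE_CODONS: dict[str, list[str]] = {}


def _sense_codons() -> dict[str, list[str]]:
    if not _SENSE_CODONS:
        from .orfs import CODON_TO_AA
        for codon, aa in sorted(CODON_TO_AA.items()):
            _SENSE_CODONS.setdefault(aa, []).append(codon)
    return _SENSE_CODONS


_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults reflect a desk-scale version of a two-tissue, two-replicate
    gonad sequencing design: 50 genes, 5,000 reads per sample, sex-biased
    genes shifted 100-fold (``bias_log10_fold = 2``), and a biased-gene
    fraction (~8%) comparable to what gonad transcriptomes show.  The
    biased fraction must stay small for ratio recovery to be meaningful:
    at 5,000 reads one read corresponds to 200 TPM, so the quiet tissue of
    a biased gene is only well-sampled while the few 100-fold-boosted
    genes do not dominate the read pool.
    """

    n_genes: int = 50
    n_biased_testis: int = 2
    n_biased_ovary: int = 2
    mean_log_tpm: float = 2.5
    sd_log_tpm: float = 0.3
    bias_log10_fold: float = 2.0
    reads_per_sample: int = 5000
    orf_length_range: tuple[int, int] = (60, 160)
    flank_length_range: tuple[int, int] = (60, 200)
    detection_prob: float = 0.8
    intensity_mu: float = 15.0
    intensity_sigma: float = 2.0
    error_rate: float = 0.0
    species: str = "speciesA"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_biased_testis < 0 or self.n_biased_ovary < 0:
            raise ValueError("biased gene counts must be >= 0")
        if self.n_biased_testis + self.n_biased_ovary > self.n_genes:
            raise ValueError(
                "n_biased_testis + n_biased_ovary must be <= n_genes")
        if self.bias_log10_fold <= 1:
            raise ValueError("bias_log10_fold must be > 1 (i.e. > 10-fold)")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be within [0, 1]")
        if self.sd_log_tpm < 0:
            raise ValueError("sd_log_tpm must be >= 0")
        lo, hi = self.orf_length_range
        if lo < MIN_PROTEIN_LENGTH:
            raise ValueError(
                f"orf_length_range lower bound must be >= {MIN_PROTEIN_LENGTH}")
        if lo > hi:
            raise ValueError("orf_length_range must satisfy lower <= upper")
        flo, fhi = self.flank_length_range
        if flo < 0 or flo > fhi:
            raise ValueError("flank_length_range must satisfy 0 <= lower <= upper")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be within [0, 1)")

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["orf_length_range"] = list(self.orf_length_range)
        data["flank_length_range"] = list(self.flank_length_range)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        for key in ("orf_length_range", "flank_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    genes: pd.DataFrame          # index gene_id: transcript, cds, protein, bias
    true_tpm: pd.DataFrame       # index gene_id: columns testis, ovary
    read_origin: dict[str, str]  # read_id -> gene_id
    sample_of_read: dict[str, SampleLabel]
    samples: list[SampleLabel] = field(default_factory=list)

    def true_log10_ratio(self, pseudocount: float = 1.0) -> pd.Series:
        t = self.true_tpm["testis"] + pseudocount
        o = self.true_tpm["ovary"] + pseudocount
        return np.log10(t / o).rename("true_log10_ratio")


def _empty_truth(samples: list[SampleLabel]) -> GroundTruth:
    genes = pd.DataFrame(columns=["transcript", "cds", "protein", "bias"])
    genes.index.name = "gene_id"
    tpm = pd.DataFrame(columns=["testis", "ovary"], dtype=float)
    tpm.index.name = "gene_id"
    return GroundTruth(genes=genes, true_tpm=tpm, read_origin={},
                       sample_of_read={}, samples=samples)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, len(_AMINO_ACIDS), size=length - 1)
    return "M" + "".join(_AMINO_ACIDS[i] for i in body)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = _sense_codons()
    parts = [codons[aa][rng.integers(0, len(codons[aa]))] for aa in protein]
    parts.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _make_transcript(rng: np.random.Generator, cds: str, protein: str,
                     flank_range: tuple[int, int],
                     max_attempts: int = 200) -> str:
    """Embed the CDS between random flanks; reject any flank pair under
    which the greedy ORF selection would not return exactly the CDS."""
    lo, hi = flank_range
    for _ in range(max_attempts):
        f5 = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        f3 = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        transcript = f5 + cds + f3
        selected = select_nonoverlapping(find_orfs(transcript))
        if (len(selected) == 1
                and selected[0].nt_start == len(f5)
                and selected[0].nt_end == len(f5) + len(cds)
                and selected[0].protein == protein):
            return transcript
    raise RuntimeError("could not place CDS between clean flanks; "
                       "widen flank_length_range or report a bug")


def simulate_transcriptome(config: SimulationConfig,
                           ) -> tuple["OrderedDict[SampleLabel, OrderedDict[str, str]]",
                                      GroundTruth]:
    """Simulate stranded read pools for 2 tissues x 2 replicates.

    Returns ``(reads, truth)`` where ``reads[sample]`` is an ordered
    ``{read_id: sequence}`` pool ready for FASTA output.  Deterministic
    under ``config.seed`` (byte-identical pools for identical configs).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = [SampleLabel(config.species, tissue, rep)
               for tissue in ("testis", "ovary") for rep in (1, 2)]
    if config.n_genes == 0:
        return OrderedDict((s, OrderedDict()) for s in samples), _empty_truth(samples)

    gene_ids = [f"g{i:03d}" for i in range(config.n_genes)]
    bias = (["testis"] * config.n_biased_testis
            + ["ovary"] * config.n_biased_ovary
            + ["unbiased"] * (config.n_genes - config.n_biased_testis
                              - config.n_biased_ovary))

    rows = []
    for gene, label in zip(gene_ids, bias):
        length = int(rng.integers(config.orf_length_range[0],
                                  config.orf_length_range[1] + 1))
        protein = _random_protein(rng, length)
        cds = _back_translate(rng, protein)
        transcript = _make_transcript(rng, cds, protein,
                                      config.flank_length_range)
        rows.append((gene, transcript, cds, protein, label))
    genes = pd.DataFrame(rows, columns=["gene_id", "transcript", "cds",
                                        "protein", "bias"]).set_index("gene_id")

    base = rng.normal(config.mean_log_tpm, config.sd_log_tpm,
                      size=config.n_genes)
    # Biased genes sit at the central abundance: the tissue shift, not an
    # extreme abundance draw, is what recovery runs are meant to measure,
    # and a 100-fold-boosted gene drawn from the upper tail would swallow
    # most of the read pool and starve every other gene of counts.
    for i, label in enumerate(bias):
        if label != "unbiased":
            base[i] = config.mean_log_tpm
    log_abundance = {"testis": base.copy(), "ovary": base.copy()}
    for i, label in enumerate(bias):
        if label == "testis":
            log_abundance["testis"][i] += config.bias_log10_fold
        elif label == "ovary":
            log_abundance["ovary"][i] += config.bias_log10_fold
    true_tpm = pd.DataFrame(index=genes.index)
    for tissue in ("testis", "ovary"):
        raw = np.power(10.0, log_abundance[tissue])
        true_tpm[tissue] = raw / raw.sum() * 1e6

    reads: "OrderedDict[SampleLabel, OrderedDict[str, str]]" = OrderedDict()
    read_origin: dict[str, str] = {}
    sample_of_read: dict[str, SampleLabel] = {}
    for sample in samples:
        p = true_tpm[sample.tissue].to_numpy() / 1e6
        counts = rng.multinomial(config.reads_per_sample, p)
        pool: "OrderedDict[str, str]" = OrderedDict()
        idx = 0
        for gene, n in zip(gene_ids, counts):
            template = genes.loc[gene, "transcript"]
            for _ in range(n):
                read_id = f"{sample.tag}_r{idx:06d}"
                idx += 1
                seq = template
                if config.error_rate > 0:
                    seq = _mutate(rng, seq, config.error_rate)
                pool[read_id] = seq
                read_origin[read_id] = gene
                sample_of_read[read_id] = sample
        reads[sample] = pool

    truth = GroundTruth(genes=genes, true_tpm=true_tpm,
                        read_origin=read_origin,
                        sample_of_read=sample_of_read, samples=samples)
    return reads, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_detections(proteins, config: SimulationConfig,
                        seed: int | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """Draw a peptide detection table from the digest of ``proteins``.

    ``proteins`` is a ``{entry_id: protein}`` mapping (or iterable of
    database entries).  Each distinct filter-passing peptide is retained
    with probability ``detection_prob`` and assigned a log-normal
    intensity.  Returns ``(table, origin)`` where ``table`` has columns
    ``peptide``/``intensity`` and ``origin`` maps each detected peptide to
    its source entries.  Deterministic under ``seed`` (default:
    ``config.seed``).
    """
    from collections.abc import Mapping as _Mapping
    if not isinstance(proteins, _Mapping):
        proteins = {entry.entry_id: entry.protein for entry in proteins}
    empty = pd.DataFrame(columns=["peptide", "intensity"])
    if not proteins:
        logger.warning("empty protein database: empty detection table")
        return empty, {}
    rng = np.random.default_rng(config.seed if seed is None else seed)
    index = enumerate_ions(proteins)
    rows = []
    origin: dict[str, frozenset] = {}
    for peptide in sorted(index.sources):
        if rng.random() >= config.detection_prob:
            continue
        intensity = float(rng.lognormal(config.intensity_mu,
                                        config.intensity_sigma))
        rows.append((peptide, intensity))
        origin[peptide] = index.sources[peptide]
    if not rows:
        return empty, {}
    return pd.DataFrame(rows, columns=["peptide", "intensity"]), origin


def write_read_pools(reads, outdir) -> list[Path]:
    """One FASTA per sample, sample identity in filename and headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, pool in reads.items():
        path = outdir / f"reads_{sample.tag}.fasta"
        write_fasta(path, pool,
                    descriptions={r: f"sample={sample.tag}" for r in pool})
        paths.append(path)
    return paths


def write_ground_truth(truth: GroundTruth, outdir) -> dict[str, Path]:
    """Headered TSVs for genes, true TPM, and the read origin map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    genes = truth.genes.reset_index()
    paths["genes"] = outdir / "truth_genes.tsv"
    write_tsv(genes, paths["genes"])
    tpm = truth.true_tpm.reset_index()
    paths["true_tpm"] = outdir / "truth_tpm.tsv"
    write_tsv(tpm, paths["true_tpm"])
    origin = pd.DataFrame(
        [(r, g, truth.sample_of_read[r].tag)
         for r, g in truth.read_origin.items()],
        columns=["read_id", "gene_id", "sample"])
    paths["read_origin"] = outdir / "truth_read_origin.tsv"
    write_tsv(origin, paths["read_origin"])
    return paths
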