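# Methods

`gonadpipe` reimplements, as a tested library, a proteogenomic analysis
chain for non-model species with no reference genome: long-read gonad
transcriptomes provide both the expression quantification and the protein
search space for sperm proteomics. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Transcript clustering and quantification

Full-length cDNA long reads (one transcript molecule per read, sense
strand) are grouped into gene-level clusters. Two routes exist:
`import_clusters` ingests the assignment table of an external greedy
clustering tool unchanged, preserving its cluster boundaries; or the
built-in `greedy_cluster` runs a simple greedy k-mer-containment pass.
The built-in pass sorts reads by descending length (ties by read id); a
read joins the first cluster whose representative (founding read) shares
at least `min_shared_fraction` (default 0.5) of the read's distinct
k-mers (default k = 15), else founds a new cluster. Representatives are
never re-centred. This is intentionally *not* a reimplementation of
quality-aware minimizer clustering: it is deterministic,
O(reads x clusters), and sufficient for error-free or low-error pools;
when fidelity to an external tool matters, use the import route. Reads
shorter than k become singleton clusters.

Cluster abundance is read count normalized per sample:
`TPM = 1e6 * count / total_reads`. No length normalization is applied —
one read is one transcript molecule. Per sample, TPM sums to 1e6 by
construction (checked to 1e-6 relative tolerance in tests).

## Sex ratio, bias calls, ranking

For one species, tissue means are taken over biological replicates and
the sex ratio of a cluster is

    log10((mean_testis_TPM + p) / (mean_ovary_TPM + p)),  p = 1.0 TPM.

The pseudocount is applied *after* replicate averaging and keeps the
ratio finite when a tissue shows zero reads. A cluster is called
sex-biased at a strict > 10-fold difference of the pseudocounted ratio,
i.e. |ratio| > 1; exactly 10-fold is unbiased. Ranking sorts ascending
(rank 1 = most ovary-biased) with lexicographic cluster-id tie-breaks.
Singleton clusters are excluded from ranking by default
(`rank_singletons=True` restores them), matching summary conventions
that report biased fractions without singletons. Report rounding is two
decimals, half away from zero.

## ORF calling and the search database

Only the three forward frames are scanned (reads are stranded). Every
ATG whose in-frame extension reaches a stop codon (TAA/TAG/TGA) before
the read end yields one candidate; candidates must encode >= 30 residues
counting the initiator Met and excluding the stop. Codons containing N
translate to X, and X counts toward length; a codon such as TAN is X,
never a stop. ATGs without a downstream in-frame stop are discarded.

Per read, candidates are reduced to "the longest possible
non-overlapping set": greedy by descending protein length, ties by
smaller start then smaller frame, overlap judged on nucleotide intervals
across frames. The greedy reading was chosen over total-coding-length
dynamic programming because it matches the emphasis on individually
longest ORFs and is deterministic; the DP alternative is not
implemented. Nested ATGs generate their own candidates and are removed
by the overlap filter when the longer ORF wins.

Identical translations are aggregated across reads; entries supported by
fewer than 2 distinct reads are dropped from the search database (the
support threshold is a parameter). Entry ids are deterministic
(descending support, then protein string).

## In-silico digestion

Trypsin cleaves after K or R except before P (the convention assumed by
downstream spectral-prediction tools); products with up to one missed
internal site are enumerated, including terminal peptides. Peptides of
7-30 residues are kept when a +2H or +3H precursor m/z falls within
396.43-1,002.70 Th, bounds inclusive — the acquired gas-phase
fractionation range. Masses are monoisotopic residue sums plus water
(18.010565 Da) with carbamidomethyl-Cys (+57.021464 Da) as the only, and
fixed, modification (iodoacetamide alkylation); the proton mass is
1.0072765 Da. Protein N-terminal Met is not removed and no semi-tryptic
peptides are produced. Identical peptide strings from different proteins
are emitted once per charge state with the full source-entry set as
provenance; peptides containing X have no defined mass and are skipped
with a log entry. Tests check the enumeration against an independent
brute-force substring oracle and the mass scale against an external
mass-spectrometry library.

## Protein groups and top-3 abundance

Observed peptides are matched to the ion index by exact string
(charge-independent); unmatched peptides are reported for QC, never
fatal. Sequence clusters receiving at least one assigned peptide are
nodes of a graph with an edge when >= 2 distinct observed peptide
sequences are shared; protein groups are the connected components.
Components are the standard parsimony reading of pairwise consolidation:
transitive and invariant to input order. Duplicate observations of one
peptide are summed into a single intensity before quantification
(summation across charge states is the implemented, configurable
choice). A group with >= 3 distinct observed peptides is quantified as
the mean of its three largest peptide intensities; smaller groups are
reported as detected but unquantified. Group abundances are normalized
to the most abundant group and ranked descending, ties by group id.
Top-3 is scale-equivariant; normalized abundances and ranks are
scale-invariant.

## Motif scanning and composition

The three-finger-protein scaffold scanner searches with the gap-bounded
cysteine pattern `.{2}C.{5,30}C.{2,20}C.{5,30}C.{2,20}C.{5,30}CC.{4}CN`
(the terminal CN being the one strictly conserved TFP feature). Search
semantics are leftmost non-overlapping matches with greedy bounded
quantifiers, unanchored; overlapping alternates are not enumerated.
Patterns are configurable by name via a flat YAML file so additional
cysteine spacings (e.g. 10-cysteine variants) need no code change. Every
reported hit is re-validated in tests by an independent character-walk
checker. The composition report counts residues and estimates net charge
as `(K + R) - (D + E)` — an integer descriptor for flagging strongly
basic candidates, deliberately not a pH-dependent charge model.

## Synthetic data: what it emulates and what it does not

The generator produces the inputs the pipeline assumes, with ground
truth attached. Genes get a random protein (length uniform in
`orf_length_range`, default 60-160 aa), a back-translated CDS with a
random stop, and random non-coding flanks (60-200 nt). Flank pairs are
rejection-sampled until the greedy ORF selection on the whole transcript
returns exactly the embedded CDS — slightly stronger than constraining
the flanks alone, and it makes ORF-recovery tests exact. Per-gene
log10-TPM is Normal(`mean_log_tpm` = 2.5, `sd_log_tpm` = 0.3); biased
genes add `bias_log10_fold` = 2 in their tissue. Read counts per sample
(two tissues x two replicates) are multinomial draws of
`reads_per_sample` = 5,000 from the normalized tissue abundances, and
reads are error-free transcript copies (an optional substitution rate,
default 0, supports clustering stress tests). Detection tables retain
each distinct filter-passing peptide of the digested database with
probability `detection_prob` = 0.8 and log-normal intensity
(ln-scale mu = 15, sigma = 2, spanning roughly three decades as ion
intensities do).

Two calibration choices deserve a note. The biased-gene fraction
defaults to 4 of 50 (~8%), comparable to the biased fractions gonad
transcriptomes show; and biased genes sit at the central base abundance
rather than drawing from the Normal. Both follow from count
granularity: at 5,000 reads one read is 200 TPM, and a 100-fold-boosted
gene drawn from the upper abundance tail can swallow most of a tissue's
read pool, starving every other gene's quiet side of counts and making
ratio recovery impossible for reasons unrelated to the estimator.
Recovery at these defaults was validated across 40 seeds (cluster count
always equal to gene count, bias sensitivity and specificity 100%,
worst biased-gene ratio error 0.19 against a 0.3 tolerance).

What the generator does *not* emulate: sequencing error profiles and
quality scores, isoform structure (one transcript per gene), chimeric
reads, homologous gene families (proteins are random, so they share no
tryptic peptides), peptide detectability models (detection is uniform
Bernoulli), and mass spectra themselves (only peptide-level
detections). Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration on clean, well-separated input —
not robustness to noisy reads or to paralog-rich databases, where the
import route for external clusterings and real search engines remain
the appropriate tools.

## Numerical and degenerate-input conventions

Zero genes yield empty pools and empty truth; an empty protein database
yields an empty detection table with a warning; a sample with zero reads
is an error naming the sample; duplicate read ids are errors naming the
read; negative TPM or intensities are errors. All randomness flows from
explicit seeds through one generator per simulation call; identical
configs and seeds give byte-identical FASTA output. Problem sizes in the
test suite (50 genes, 20,000 reads, 200-protein oracle sweeps) were
chosen as the smallest at which the recovery properties are
statistically comfortable, and the whole suite runs in a few seconds.
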