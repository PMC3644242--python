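# Methods

## Coordinate system and the domain model

All AP2-domain positions are expressed on a fixed 58-position structural
numbering anchored to the AtERF1 DNA-binding domain: positions 145–202,
plus an insertion slot `167i` between 167 and 168 that is occupied only
in ERF group IX (giving that group a 59-residue domain). Internally the
position-specific model uses model positions 1–58 with
`structural = model + 144`; structural numbers appear in all reports.
Sequence intervals are 0-based half-open everywhere in memory; the miRNA
report uses 1-based inclusive positions, matching the field's table
conventions.

The AP2 (and B3) detector is a log-odds position-specific scoring model
built over a labelled reference alignment with additive pseudocounts
(default 0.5) against a uniform background, scored in bits. Alignment of
a model to a peptide is semi-global: peptide flanks are free, model
flanks are free only at a peptide end (domains truncate at sequence
ends, so a partial domain must abut a boundary), internal model
deletions pay an affine penalty (open 4.0, extend 1.0 bits), and a
single-residue peptide insertion is allowed only at the `167i` slot
(penalty 2.0 bits). General peptide insertions are not modelled: the
transcripts this tool targets are assembled contigs, not reads with
frameshift errors.

A hit is accepted when its score reaches 60% of the maximum attainable
over the matched model span (the full-model maximum when the span covers
both ends) and the span covers at least 16 model positions. Normalizing
to the matched span rather than the full model keeps truncated domains
detectable under one rule; the short/soloist architecture — spanning
both ends with ≥4 internal deletions — is still scored against the
full-model maximum, which it passes comfortably. Completeness classes:
`full` (span 1–58, <4 internal deletions), `short` (span 1–58, ≥4
deletions), `partial_N` / `partial_C` / `partial_both` (truncations).
Multiple domains per peptide are found greedily, best score first, with
matched columns masked between rounds; ties resolve to the leftmost end.

## Family classification

Domain architecture decides the family: two AP2 domains → AP2 family;
one AP2 plus one B3 → RAV; one short AP2 → soloist; one full or partial
AP2 → ERF, unless the homology override applies. The override routes
single-domain genes to the AP2 family when their anchored domain is
closer (p-distance over shared positions) to the AP2-family reference
repeats than to any ERF reference. Profile log-odds scores were rejected
for this comparison because pseudocount shrinkage biases scores toward
the larger reference set (55 ERF vs 12 AP2 references);
nearest-reference identity is size-unbiased. A tie resolves to ERF — the
override requires positive evidence.

## Group assignment

ERF groups (I–X, VI-L) are assigned by placing each query on a
neighbour-joining tree together with the labelled reference panel:

1. anchored domains are curated into a conserved block (a column is kept
   when its modal non-gap residue covers ≥50% of rows; maximal runs of
   ≥10 conserved columns are retained — the sparsely occupied `167i`
   column drops out and the flanking runs both qualify);
2. p-distances are computed over mutually non-gap block columns;
3. Saitou–Nei agglomeration with a deterministic lowest-index tie-break;
   negative branch-length estimates are clamped to zero and counted;
4. the tree evidence is the majority reference label of the query's
   smallest enclosing reference-containing clade.

The group-diagnostic residue profile is recorded as secondary evidence:
the most specific marker set fully present in the query (so a VIII
domain carrying P153+K168 does not resolve to V or VI, whose sets are
subsets). When the unique marker match contradicts or disambiguates the
tree placement, the markers decide and the `method` field says so;
otherwise the call is `tree+markers` or `tree`. Partial-domain ERF genes
are grouped by nearest-reference homology only and are excluded from the
full-domain group inventory. Subgroup letters (VIIa, IXb, …) are labels
carried from the nearest reference, never inferred from sequence. For
display, the joint tree is built from the first (R1) AP2 repeat of
double-domain genes, falling back to R2 when R1 is absent.

## Marker discovery

"Group-specific residue" is operationalized as a consensus deviation.
For each position, the background residue is the modal state of the
largest number of groups. A residue is reported as a marker for a group
when (i) it differs from the background, (ii) the group's non-background
residues jointly reach `within_min` (default 90%), (iii) it occurs in
each background-conforming group at ≤ `outside_max` (10%), and (iv) it
is the modal state of at most `max_shared_groups` (3) groups. The
sharing cap separates genuine group markers shared by two groups (G168
in IV and VII; K168 in V and VIII; P153 in VI and VIII) from the
four-group DREB diagnostics V158/E163, which belong to the subfamily
channel. Group IX is reported through the `+X167` occupancy rule rather
than a substitution. Residues with a within-group frequency of ≥5% are
listed individually, which is how the AP2 family's split T150/A150
marker is reported with both frequencies. The defaults admit the
92–100% conservation range markers exhibit in practice.

Universal residues are positions where one residue reaches the
conservation threshold (default 100%) in every ERF group; the DREB/ERF
subfamily call is V158∧E163 → DREB, A158∧D163 → ERF, otherwise
UNRESOLVED with tree placement as the caller's fallback. Motif scans are
literal (YRG, WLG, RAYD, KREYD) except the EAR repression motif, which
uses the consensus pattern `(L/F)DLN(L/F)xP` held in one overridable
constant.

## Tissue expression and qPCR

Read membership is aggregated into a contigs × libraries count matrix;
group × tissue tables carry row/column margins and a grand total, and
cells always sum to their margins under partition refinement. Tissue
shares are percentages of the total, rounded half-up to one decimal (the
printed precision), so shares sum to 100 ± 0.3. The qPCR normalized
ratio is efficiency-corrected, `E_t^(−Cp_t) / E_r^(−Cp_r)`, with
amplification factors defaulting to 2.0 per cycle — reducing to
`2^−ΔCp` — and validation bounds Cp ∈ (0, 60), E ∈ (1, 2.2]. No
differential-expression testing is reimplemented; the count matrix is
exported in a layout such packages consume.

## miRNA target prediction

Penalties are counted per miRNA position from the 5' end: gap 2,
non-pairing position 1, G:U wobble 0.5; acceptance requires total ≤ 3,
≥15 aligned columns, pairing (Watson–Crick or wobble) at protected
positions 10–11, and duplex energy ≤ −20 kcal/mol. Because one gap costs
2, an accepted alignment holds at most one gap; the scanner enumerates
the gapless alignment and every single-bulge variant exactly with
vectorized prefix/suffix penalty sums, rather than a heuristic DP.
Duplex energy is a deliberately simple additive per-pair model (G:C
−3.0, A:U −2.0, G:U −1.0, non-pair/gap 0), exposed as one overridable
table; it is *not* a nearest-neighbour stacking model and is not
expected to reproduce energies from thermodynamic tools — only the −20
kcal/mol acceptance bound is contractual, and published example
fragments clear it with margin. Inhibition mode follows the
central-pairing convention of plant target-prediction servers:
Watson–Crick pairing across positions 9–11 → cleavage, otherwise
translational repression; this is a documented convention, not a claim
about how any particular study derived its calls. Site regions (5'UTR,
CDS before/inside/after the AP2 domain, 3'UTR) are labelled by the
site's midpoint relative to the CDS and the leftmost AP2 domain.

## The synthetic cohort

The generator emulates the structure the analysis assumes, with defaults
set to the published inventory: 25 AP2 genes (9 two-full, 4
full+partial, 2 two-partial, 7 one-full, 3 one-partial), 141 ERF (115
full-domain split 12/7/11/3/5/5/23/15/19/9/6 across groups I–X and VI-L,
plus 26 partial), 4 RAV, 3 soloists — 173 genes, 142 with a complete
domain. Tissue weights default to the published read shares
(root 0.298, bark 0.222, latex 0.212, embryogenic 0.164, leaf 0.104).

Domains derive from a 58-residue consensus scaffold carrying the YRG,
WLG and RAYD elements and the ten universal residues; group domains add
their diagnostic residues, DREB groups the V158/E163 state, group IX a
planted `167i` insertion, VI-L the KREYD element (K189 against the
scaffold's own REYD, frozen in that group). Soloists delete the six
consecutive positions 149–154 (including R152); the identity of the six
is a design choice, as only R152 is pinned down externally. Every other
position drifts to a fixed minor residue at rate 0.05 per gene (0.02 in
the reference panel), and each variable position is additionally forced
to its minor state in exactly one non-VI-L ERF gene so that, at the 100%
threshold, exactly the ten universal positions survive regardless of
seed. AP2-family repeats carry T150 (one reference in twelve carries
A150) plus a six-position family signature planted at 85% — deliberately
below the 90% marker-discovery threshold, so T150/A150 remains the
family's only reported marker while the homology override rests on
several columns. Coding sequence uses uniformly random synonymous
codons; UTRs (50–300 nt) and coding pads are random; every third gene is
reverse-complemented to exercise strand handling. Partial domains are
truncated at a transcript end (20–45 model positions kept; AP2-family
partials keep ≥28 so position 150 and part of the signature survive).

Reads are allocated multinomially over genes × tissues with lognormal
gene weights (total 6318 by default). miRNA sites (24 by default, 21
nt) are planted alternately as cleavage-type (WC across 9–11, every
fourth a perfect complement, otherwise one mismatch at position 15) and
translation-type (a non-pairing base opposite position 9). In-domain
sites straddle the domain boundary — midpoint just inside, roughly half
the window in the unique flank — because a window wholly inside the
conserved domain would make the derived miRNA cross-hybridize to
paralogous domains (synonymous third-position transitions score as 0.5
wobbles). Sites are planted only on plus-strand transcripts, since a
minus-strand contig's mRNA is its reverse complement and region labels
in contig coordinates would be ill-defined.

What the generator does **not** emulate: 454 sequencing error profiles,
homopolymer errors and frameshifts, assembly chimerism, allelic
variation, realistic codon usage and UTR composition, biological
correlation between group membership and expression, and thermodynamic
duplex energetics. Passing tests therefore demonstrate the pipeline's
correctness on clean, structurally faithful data — its contracts, not
its robustness to sequencing artifacts, which the surrounding tooling
(assembly, frame correction) is assumed to have handled.

## Problem sizes and runtime

The default cohort (173 genes, ~1–2 kb transcripts) runs end to end in
well under a minute on one CPU: six-frame scanning dominates (~700
peptide candidates × a vectorized 58-row DP), group assignment runs one
56-taxon NJ per query, and the miRNA stage scans 24 miRNAs × 173
contigs with O(m·n) vectorized penalty sums. Tests run the full cohort
once (session fixture) plus a reduced cohort (39 genes) for the
file-level pipeline checks; the topology property tests enumerate all
unrooted topologies at n = 4 and 5 with least-squares branch fitting as
the independent oracle.

## Known limitations

- The scanner assumes in-frame, stop-free domains; frameshifted or
  chimeric contigs are out of scope.
- Marker discovery reports within-group conservation of the synthetic
  panel; the published percentages for groups II/VIII (97–98%) reflect a
  three-species panel that is not packaged, so the shipped panel plants
  those markers at 100% and the comparison is on positions/residues/
  groups, not percentages.
- Branch supports (bootstrap, aLRT) and maximum-likelihood trees are not
  computed; NJ with marker corroboration is sufficient for the
  classification contract on clean data.
- The energy model is additive per pair; absolute energies are not
  comparable to nearest-neighbour tools.
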