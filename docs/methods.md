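# Methods

## Overview

`proteasim` predicts how well a set of proteolytic enzymes — alone or in
combination — will characterise a proteome or a protein subset in a
bottom-up LC-MS experiment, before any sample is prepared. The prediction
is a Monte-Carlo simulation that mirrors the experimental chain: sample
composition (which proteins are present and how abundant they are),
proteolytic digestion with realistic missed-cleavage behaviour, the
semi-stochastic selection of peptides by the mass spectrometer, and
protein inference from the identified peptides. Each protease
combination is then summarised by a single *protease score* relative to
a control digestion.

## The protease score

For a protein group $G$ (by default: small proteins of at most 70
residues versus everything larger) and a workflow $A$,

$$
S_{G,A} = \left[
  \left(\frac{(N_\mathrm{Prot})_{G,A}}{(N_\mathrm{Prot})_{G,C}}\right)^{W_\mathrm{Prot}}
  \left(\frac{(N_\mathrm{Pep})_{G,A}}{(N_\mathrm{Pep})_{G,C}}\right)^{W_\mathrm{Pep}}
  \left(\frac{\mathrm{COV}_{G,A}}{\mathrm{COV}_{G,C}}\right)^{W_\mathrm{COV}}
\right]^{1/(W_\mathrm{Prot}+W_\mathrm{Pep}+W_\mathrm{COV})}
$$

where $N_\mathrm{Prot}$ is the number of identified proteins in $G$,
$N_\mathrm{Pep}$ the number of identified peptides belonging to those
proteins, $\mathrm{COV}$ their mean sequence coverage, and $C$ the
control workflow (tryptic digestion unless configured otherwise). The
weighted geometric mean keeps the three heterogeneous metrics on a
common, ratio-based scale; $S > 1$ means $A$ beats the control under the
chosen weights (default $1,1,1$). Scores are computed per Monte-Carlo
round with *paired* normalisation — workflow and control metrics come
from the same virtual sample — so between-sample abundance noise cancels
out of the ratio. Whether to pair per round or normalise against the
control's across-round mean was a genuinely open choice; pairing was
selected because it strictly reduces the variance of the reported score
without changing its expectation under exchangeable rounds. If a control
metric is zero in some round the score for that cell is NaN; NaN rounds
are excluded from the summary statistics and counted in `n_nan`.

## Virtual samples

Protein abundances are unknown before the experiment but dominate
peptide detectability, so each round draws a fresh abundance for every
protein from a log-normal distribution (default location 0, log-SD 2.0 —
about four orders of magnitude, a configurable stand-in for the abundance
span of bacterial cells). A configured fraction of each protein group is
set *absent* (abundance zero) in every round; the default of 45%
reflects typical proteome coverage in a bacterial whole-cell experiment.
The fraction is applied as an exact half-up-rounded count per group, not
a per-protein coin flip, so a 45% fraction on 1000 small proteins zeroes
exactly 450 of them in every round; this makes the absent-protein count
deterministic and tests exact. Per-round RNG seeds are
`master_seed + sample_index`, so any single round can be reproduced in
isolation.

## Digestion and peptide mapping

Digestion is rule-based: a protease is a set of recognised residues, a
cut side (C- or N-terminal of the match), and an optional set of
blocking residues immediately after the cut position (proline for
trypsin and chymotrypsin by default; `trypsin/p` and
`chymotrypsin-strict` variants expose the other common conventions).
With internal boundaries $b_1<\dots<b_c$, the fully cleaved peptides are
the $c{+}1$ inter-boundary fragments and an $m$-missed-cleavage peptide
is any concatenation of $m{+}1$ consecutive fragments, enumerated up to
`max_mc` (default 5). Peptides are filtered to a detection window of
6–45 residues and 400–6000 Da (inclusive, uncharged monoisotopic mass
from standard residue masses plus one water); peptides containing
ambiguity codes (X, B, Z, ...) are discarded with a logged count so that
coordinates stay intact while masses stay defined.

Kept peptides are mapped back to the *whole* database as plain
substrings, deliberately ignoring which protease generated them:
semi-specific cleavage is common in practice, so a peptide that is
unique only under the assumption of specific cleavage can produce
false-positive identifications. A peptide is unique iff it matches
exactly one position database-wide (overlapping matches inside one
protein count separately); non-unique peptides are dropped by default
but can be retained for the shared-peptide mode. Mapping uses a k-mer
(k=5) positional index with candidate verification, which reproduces a
naive sliding-window scan exactly. I and L are treated as distinct
letters; no I/L-equivalence is applied. Identical sequences produced by
different proteases are tracked once per protease, matching a design in
which each digest is measured in its own LC-MS run. A sequence generated
at several positions or MC levels by the same protease is tabulated once
with its minimum MC count (the most parsimonious generation route).

## Simulated measurement

Per virtual sample and per protease, the configured number of identified
peptides (default 10 000; the bundled demonstrations use 2000 to match
their smaller proteome) is first split across missed-cleavage bins
according to the protease's expected MC frequency profile —
largest-remainder rounding, so 10 000 peptides at a 5% one-MC fraction
give exactly 9500 + 500. Bins whose pool is empty are reallocated
proportionally to the remaining bins' fractions; bins are additionally
capped at their pool size with the excess redistributed the same way, so
the requested total is conserved whenever the overall pool suffices (an
overall shortfall is logged and yields the whole pool). The bundled MC
profiles are qualitative stand-ins (Arg-C nearly complete; chymotrypsin
mostly uncut; trypsin and LysArgiNase intermediate with wide
protocol-dependent spread) and should be overridden with
protocol-specific numbers when available.

Each bin is then sampled *without replacement* with probability
proportional to peptide weight: the summed abundance of the peptide's
source proteins, optionally multiplied by a detectability score. A
peptide can be identified at most once per virtual measurement, which is
why sampling is without replacement; a with-replacement switch exists
for sensitivity analysis. The sampler uses the Efraimidis–Spirakis
exponential-key construction (take the $n$ smallest $\mathrm{Exp}(1)/w_i$
arrival times), which is equivalent in distribution to drawing
sequentially with probability proportional to weight among the remaining
candidates, and is fully vectorised. Zero-weight peptides (absent
proteins) are never drawn. Sub-seeds per (sample, protease) derive
deterministically from the master seed and the protease name, so a
protease subset reproduces identically regardless of which other
proteases are simulated alongside it.

## Protein inference and combinations

A protein is identified when at least `min_unique` distinct sampled
unique peptides map to it; results are reported for both the lenient
1-unique rule and the stricter two-unique-peptides rule. Sequence
coverage is the union of the sampled peptides' residue intervals divided
by protein length; identified-peptide counts include only peptides of
identified proteins.

Protease combinations emulate separately measured digests of one sample:
within a round, the identified-protein sets of the member proteases are
unioned, peptide counts summed, and coverage recomputed from the union
of intervals across members. With the uniqueness filter off
(metaproteomics-style data), proteins sharing exactly the same sampled
peptides form protein groups; a peptide is group-unique when all its
occurrences fall inside the group, and group coverage and peptide counts
are the medians over members. Because per-protease protein groups are
not comparable objects across proteases, shared-mode combinations pool
the member digests and re-run group inference on the pool. A group's
length-class label is the majority label of its members (ties broken by
database order).

## Detectability

Physicochemical detectability can modulate the sampling weights in three
modes: `uniform` (neutral, the default), `file` (a two-column TSV from
any external predictor; missing peptides fall back to a neutral 1.0 with
a warning so none are silently excluded), and `heuristic` — a
deterministic surrogate
`clip(1 − 0.04·max(0, 8−L) − 0.02·max(0, L−20), 0.05, 1) ·
clip(1 − 0.15·(|GRAVY| − 1.5)₊, 0.05, 1)` that penalises extreme lengths
and extreme Kyte–Doolittle hydropathy while never zeroing a peptide. The
multiplication of abundance by detectability is the package's own
modelling choice for how the two factors combine.

## Synthetic proteomes

The bundled generator writes reproducible FASTA databases with an exact
small-protein count (`round(small_fraction · n)`), lengths uniform in
20–70 (small) and 71–450 (large) residues, and i.i.d. residues at
approximately bacterial average frequencies, so every catalogued
protease encounters realistic site densities. It emulates the
combinatorics of a real database — length classes, substring-level
peptide sharing, per-protease site densities — but *not* homology:
real proteomes contain paralog families with long identical stretches,
so real uniqueness rates are lower and protein grouping is more
prevalent than in synthetic runs. Passing tests on synthetic data
therefore validate the machinery and the direction of the main trends,
not organism-specific score magnitudes.

## Problem sizes and observed behaviour

The test-suite and acceptance-script demonstrations run 1000 proteins
(30% small), five proteases (trypsin, Lys-C, chymotrypsin, Glu-C,
LysArgiNase), 2000 sampled peptides per protease and ten Monte-Carlo
rounds — sizes chosen so a full run finishes in well under a minute on
one CPU while keeping per-round identification counts in the hundreds.
Under these conditions the simulation reproduces the qualitative
behaviour expected of multi-protease designs: mean scores increase with
the number of combined proteases with clearly diminishing returns (the
second protease adds more than the third), and small-protein scores are
several-fold less stable between rounds than large-protein scores.

The contrast between MC-adjusted and complete-digestion (0-MC)
predictions at fixed peptide counts shows a small mean score decrease
for small proteins under the default demonstration seeds. This effect is
weak on a homogeneous synthetic proteome — of the same order as the
between-realization noise of the generator — so its sign should not be
expected to persist across arbitrary generator seeds; on real proteomes
the effect is driven by organism-specific sequence composition that the
i.i.d. generator does not model.

## Numerical choices and edge cases

- Largest-remainder ties in bin allocation break toward the lower MC bin.
- Monoisotopic residue masses come from the standard tables bundled with
  the mass-spectrometry utilities used for parsing (summed per protein as
  prefix sums, so per-peptide mass is O(1)); water is 18.0105646863 Da.
- Score weights may be any non-negative reals, not all zero; scaling all
  weights by a constant leaves the score unchanged.
- Peptide tables are written with `%.17g` floats and read with
  round-trip float parsing, so write→read is an exact identity.
- An empty FASTA, a duplicate protein id, overlapping or gapped group
  intervals, and a non-numeric abundance cell in an edited prep table are
  all fatal with messages naming the offending entry or line.
- Degenerate inputs: a protein with no cleavage sites digests to itself
  with 0 MCs; `undetectable_fraction` 0 and 1 produce all-present and
  all-absent samples; a request larger than the positive-weight pool
  returns the whole pool with a logged shortfall.

## Known limitations

- No modelling of retention time, co-elution, fragmentation quality,
  charge states, modifications, or FDR; detectability is either external
  or a coarse heuristic.
- The MC frequency profiles and the abundance distribution defaults are
  documented stand-ins, not measured values; both are fully configurable
  and should be calibrated per protocol.
- Semi- and non-specific peptides are handled at the mapping/uniqueness
  level only; they are not enumerated as sampleable peptides.
- Scoring a *single* protein of interest is out of scope; the score is
  defined over protein groups.
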