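# oncosieve

Statistical sieving of somatic mutation catalogs in coding genes: are the
mutations in a gene *selected* (dN/dS), *clustered* along the protein or in
3D space (hotspots), and do alterations in different genes *avoid or attract
each other* across patients?

The package grew out of the analysis needs of tumour-cohort studies of
ion-channel gene families (e.g. the KCNQ voltage-gated potassium channels in
gastro-oesophageal adenocarcinoma), where the evidence that a gene is a
driver rests on exactly these signals rather than on raw mutation counts.
It is aimed at computational cancer-genomics practitioners who have a
MAF-like mutation table, per-sample copy-number calls and a coding sequence,
and want calibrated, permutation- or enumeration-backed answers at desk
scale. A synthetic-cohort generator with known ground truth (planted
hotspots, planted selection, planted mutual exclusivity, planted spatial
clusters) makes every test verifiable end to end.

## What it computes

**Copy-number classification.** For gene *g* in sample *s* with total copy
number *c* and sample ploidy *π*: rel = log₂(c/π); the gene is *deleted* if
c = 0 or rel < −1, *amplified* if rel > 1 (strict inequalities). Calls are
assembled into a patients × genes alteration matrix together with
missense/truncating mutation calls.

**Signature-driven expectations.** Mutations are tallied into the 96-channel
trinucleotide spectrum (COSMIC pyrimidine-centred convention); a signature
is refit either by pseudocount smoothing or by non-negative least squares
against a reference catalog. From a signature, every possible single-base
substitution in a CDS gets a relative rate, which yields (i) the expected
per-residue mutation profile and (ii) a sliding-window (default 50 bases)
observed/expected ratio track along the gene.

**1D clustering (NMC).** With *m* mutated residue positions on a protein of
length *N*, the span between order statistics *k* < *l* follows
Beta(l−k, m−l+k+1) under uniform placement. All m(m−1)/2 pairs are tested
(exact discrete-uniform null for small problems, a conservative
continuity-corrected Beta bound for large scans) and BH-adjusted; clusters
with *q* < 0.05 are reported.

**3D clustering.** A weighted-average-proximity score
Σ_{i<j} nᵢnⱼ·exp(−d²ᵢⱼ/2t²) over Cα coordinates (t = 6 Å), with a
permutation null that reassigns the observed mutation counts to random
residues.

**Selection (dN/dS).** e_N and e_S are the signature-weighted rate masses of
nonsynonymous and synonymous sites; conditioning on the observed total, the
nonsynonymous count is Binomial(n+s, e_N/(e_N+e_S)) under neutrality.
ω = (n/e_N)/(s/e_S), with a two-sided exact binomial p and BH correction
across genes; ω > 1 with q < 0.05 flags positive selection.

**Mutual exclusivity / co-occurrence.** A curveball-trade permutation null
that preserves every patient's alteration burden and every gene's frequency
exactly; per gene pair, left/right tail p-values on the overlap with BH per
direction.

## Worked example

```python
from oncosieve import Signature, context_dnds, cohort_dnds, scan_clusters, site_rates
from oncosieve.synthetic import SimConfig, gen_cds, gen_mutations

config = SimConfig(seed=7, cds_length_codons=400, n_mutations=300,
                   hotspot=(120, 124, 15.0), omega_true=3.0)
cds = gen_cds(config)
mutations, truth = gen_mutations(cds, config)

rates = site_rates(cds, Signature.uniform())
table = cohort_dnds([context_dnds(mutations, rates)])
print(table[["gene", "n_obs", "s_obs", "omega", "p", "q", "flag"]].round(3).to_string(index=False))

positions = [m.residue for m in mutations if m.consequence == "missense"]
top = scan_clusters(positions, cds.n_residues)[0]
print(f"top cluster: residues {top.start_residue}-{top.end_residue}, "
      f"{top.member_count} mutations, q = {top.q:.3g}")
```

```
 gene  n_obs  s_obs  omega   p   q  flag
GENE1    275     25  3.553 0.0 0.0  True
top cluster: residues 120-124, 42 mutations, q = 5.42e-27
```

The simulated gene carries 3× nonsynonymous enrichment and a 15× hotspot at
residues 120–124; the selection test estimates ω ≈ 3.6 and flags the gene,
and the cluster scan pins the top cluster exactly onto the planted span.

The same stages are exposed as a CLI (`oncosieve simulate | spectrum |
expect | track | nmc | cluster3d | dnds | cnclass | cooccur | report`); each
subcommand writes its outputs plus a run manifest under `--outdir`.

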