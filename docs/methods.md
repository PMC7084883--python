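# Methods

## Model overview

The package estimates yields of clustered DNA damage from the spatial
pattern of inelastic electron interactions ("events") in liquid water,
without any explicit DNA geometry. Three statistics of an event cloud
carry all the information used:

* `N_event` — the number of events (ionizations and excitations count
  equally; the kind label is stored but never weighted);
* `N_link(L_c)` — the number of unordered event pairs separated by at
  most the inter-lesion distance `L_c`;
* `N_cl` — per linkage *site* (pair midpoint), the number of events
  within `L_c` of the site centre, the pair included.

Yields follow linearly: `Y_SSB = k_SSB·N_event/E_dep`,
`Y_DSB = k_DSB·N_link(10 bp)/E_dep`, and the base-damage analogues
`Y_BD = k_BD·N_event/E_dep`, `Y_cBD = k_cBD·N_link(L_c)/E_dep`. The
coefficients carry every unit conversion (keV·Gy⁻¹·Da⁻¹); no separate
dose or DNA-mass bookkeeping is attempted. `k_BD = 1.3·k_SSB` and
`k_cBD = 1.3²·k_DSB` encode the assumption that base damage is induced
1.3 times as readily as a strand break, per lesion — hence the model
identity `Y_BD/Y_SSB = 1.3` on every event set, and `η²` for detecting
the two lesions of a cBD site.

## Conventions and numerical choices

* **Distances are closed**: a pair at exactly `L_c` links; an event at
  exactly `L_c` from a site centre counts toward `N_cl`. The
  bp→nm conversion is fixed at 0.34 nm/bp (10 bp = 3.4 nm).
* **Linkage convention**: all in-range unordered pairs count, so one
  event may belong to several linkages. This is deterministic,
  order-independent, and invariant under rigid-body transforms. A
  greedy `unique` pairing mode (shortest distances first, each event
  used once) is available for sensitivity analysis.
* **Site centre** is the pair midpoint — the unique symmetric choice.
  Because the pair lies within `L_c/2` of its midpoint, `N_cl ≥ 2`
  always.
* **Neighbor search** uses a k-d tree (`scipy.spatial.cKDTree`) but is
  contractually exact: the test suite checks equality with an O(n²)
  brute-force scan on random event sets up to 2000 events. No
  approximate search is permitted.
* **Classification bins** are half-open integer ranges starting at
  `N_cl = 2`. The BD-family scheme uses width 9 (events per additional
  base damage); the strand-break scheme uses width
  `round(9 × 1.3) = 12`, computed at scheme-construction time from the
  BD spacing and the BD/SSB ratio rather than hard-coded. Sites with
  `N_cl` at or above the top edge (29 / 38) are reported in a separate
  overflow fraction so that fractions plus overflow sum to exactly 1;
  when yields are split over classes the overflow mass is folded into
  the most complex class so the split sums to the parent yield.
  Fractions are normalized per site (each linkage contributes once),
  with no cluster deduplication.
* **Degenerate inputs**: an empty event set yields an `empty`-flagged
  report with zero yields; a non-empty set with zero deposited energy
  is impossible (the 1 eV transport cut-off is enforced at parse and
  construction time) but would raise an undefined-yield error.

## Detection corrections

A damage class containing k base damages is detected with probability
η^k under independent per-lesion labelling; this generalizes the two
stated special cases Y_BD·η and Y_cBD·η² and is the default
(`mode="per_lesion"`). A strict `parent_only` mode scales only Y_BD
and Y_cBD. Under per-lesion thinning the corrected BD-stream class
yields (η², η³, η⁴) no longer sum to η²·Y_cBD; conservation holds for
the uncorrected report only. Strand-break yields are never scaled.

The probe-size loss `Y*_cBD = Y_cBD(10 bp) − Y_cBD(5 bp)` models the
~10 bp diameter of an ARP-streptavidin label: two base damages closer
than 5 bp merge under one probe. It applies to the cBD (pure-BD
family) yield only, not to the DSB±BD classes, which the AFM analysis
resolves through the strand-break end. Linkage monotonicity in `L_c`
guarantees the loss is non-negative on any single event set; the
implementation rejects a 5 bp yield exceeding the 10 bp one as a
provenance mismatch.

## Synthetic track generator

The generator replaces a physical transport engine with the minimal
model that still spans the method's input space: events along an
isotropic random walk with exponentially distributed step lengths
(mean = the mean free path), per-event deposits from a normal
distribution truncated at the 1 eV cut-off, and an independent
ionization/excitation label. Defaults — 1000 events, 5 nm mean free
path, deposits ~ N(30 eV, 10 eV), ionization probability 0.5 — are of
the order seen for electrons slowing down in liquid water, where
inelastic mean free paths are nanometres to tens of nanometres and
mean energy losses are a few tens of eV per collision.

What the generator reproduces: controllable event density (hence
linkage counts and cluster-size spectra), exact event counts, seeded
bit-reproducibility (numpy PCG64), and the qualitative trend that
denser tracks produce larger clusters and more complex damage. What it
does not: real energy-dependent cross sections, secondary-electron
cascades, track-end density enhancement, or any correlation between
step length and energy loss (the yield equations only use the energy
sum, so geometry–energy correlation is irrelevant to them). Passing
tests therefore validate counting, classification and correction
logic and internal trends — not absolute yields for any real
radiation quality, which depend entirely on the transport physics
that produces the event coordinates.

`generate_blob` places n events uniformly in a ball; with radius ≤
`L_c/2` every site has `N_cl = n` exactly, which is how the
classification bins are tested without statistical slack.

## Design choices on genuinely open points

* Whether events may participate in multiple linkages is not fixed by
  the damage-site picture; the all-pairs convention was chosen for
  determinism and dense-cluster consistency, with the greedy unique
  matching behind a switch (results in this package's reports use
  all-pairs unless stated).
* `f(N_cl)` is normalized over sites, not over a deduplicated cluster
  set: overlapping sites in a dense cluster each contribute, which
  weights fractions by pair multiplicity. The brute-force recount in
  the tests uses the same convention.
* The 1 eV cut-off is the sole event filter; no additional
  energy-threshold damage-induction rule is applied.
* The strand-break yields entering the complex-DSB ratio
  (cDSB/DSB = 100·(DSB⁺+DSB⁺⁺)/(DSB+DSB⁺+DSB⁺⁺)) come from the
  SB-scheme split of `Y_DSB`; any common normalization cancels in the
  ratio.

## Known limitations

* No explicit DNA target geometry: strand assignment, chromatin
  structure and damage induction probabilities are absorbed into the
  calibrated coefficients, which are only valid for sparsely ionizing
  (electron/photon) radiation.
* The maximum observed `N_cl` classes top out at 4 lesions; denser
  radiation qualities (high-LET ions) would overflow the schemes, and
  the overflow fraction should be inspected before trusting the class
  split.
* The per-lesion η generalization assumes independent labelling of
  each base damage; cooperative or steric labelling failures are not
  modelled beyond the 5 bp probe-loss subtraction.
* Yield ratios between cBD and DSB inherit `k_cBD/k_DSB = 1.3²`
  exactly whenever both use the same linkage count; published
  energy-dependent maxima of the two yields can differ from this
  ratio (e.g. when maxima occur at different energies), and this
  package makes no attempt to resolve that.

## Problem sizes

Default test and acceptance runs use synthetic tracks of 10²–2×10³
events and brute-force cross-checks up to 2000 events — sizes at which
the O(n²) oracle is exact and fast while the k-d tree path is already
exercised well past any small-n special case.
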