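# trackdamage

Clustered DNA damage yields from electron track-structure events.

Ionizing radiation kills cells mainly through *complex* DNA damage — two
or more lesions (strand breaks, base damages) within about 10–20 base
pairs. Such nanometre-scale lesion clustering cannot be observed
directly, but it correlates with the spatial aggregation of the
inelastic events (ionizations and electronic excitations) along the
charged-particle track. `trackdamage` implements a simplified cluster
analysis of such event clouds for radiation biophysicists: it turns a
table of event coordinates into yields and type fractions of
single-strand breaks (SSB), double-strand breaks (DSB), base damage
(BD), clustered base damage (cBD) and the complex classes built from
them (DSB/BD, DSB/BD/BD, 2BD…4BD, DSB+/DSB++), including the
corrections needed to compare with enzymatic-cleavage and atomic force
microscopy (AFM) experiments.

## The model

From an event set with `N_event` events depositing `E_dep` keV, and
`N_link(L_c)` linkages (event pairs within the inter-lesion distance
`L_c`, 10 bp = 3.4 nm by default), the yields in Gy⁻¹Da⁻¹ are

    Y_SSB = k_SSB · N_event / E_dep        Y_DSB = k_DSB · N_link(10) / E_dep
    Y_BD  = k_BD  · N_event / E_dep        Y_cBD = k_cBD · N_link(L_c) / E_dep

with k_SSB = 5.66×10⁻¹² and k_DSB = 1.61×10⁻¹³ keV·Gy⁻¹·Da⁻¹
(calibrated against 220 kVp X-ray strand-break yields), and the
base-damage coefficients derived from the BD/SSB induction ratio 1.3:
k_BD = 1.3·k_SSB = 7.36×10⁻¹², k_cBD = 1.3²·k_DSB = 2.72×10⁻¹³.

Each linkage defines a damage *site*; the number of events within
`L_c` of the site midpoint, `N_cl`, measures the local event density
and is binned into damage classes:

| N_cl      | DSB stream | cBD stream |   | N_cl      | SB stream |
|-----------|------------|------------|---|-----------|-----------|
| [2, 11)   | DSB        | BD/BD      |   | [2, 14)   | DSB       |
| [11, 20)  | DSB/BD     | BD/BD/BD   |   | [14, 26)  | DSB+      |
| [20, 29)  | DSB/BD/BD  | BD/BD/BD/BD|   | [26, 38)  | DSB++     |

The bin width 9 is the mean number of events needed to add one BD to a
site; the strand-break bins are 12 = round(9 × 1.3) wide, since a
strand break is 1.3 times as costly as a base damage. The fractions
f(N_cl) split `Y_DSB` and `Y_cBD` over the classes.

Two experimental detection effects are modelled: a per-BD labelling
efficiency η (Y_BD·η, Y_cBD·η², and η per BD in a class), and the
probe-size loss of ARP/AFM imaging, `Y*_cBD = Y_cBD(10 bp) − Y_cBD(5 bp)`
— two base damages closer than 5 bp hide under one ~10 bp probe.

Because absolute yields depend on the (external) track-structure
transport physics, the package ships a seeded synthetic track
generator — an isotropic random walk with exponential step lengths —
that controls event density directly and makes the entire pipeline
testable and reproducible on its own.

## Worked example

```sh
trackdamage simulate --n-events 1000 --mean-free-path-nm 3 --seed 7 --out track.tsv
trackdamage analyze --input track.tsv --eta 0.9 --arp-loss \
    --out report.json --table classes.tsv
trackdamage report report.json
```

The simulated track has 1000 events depositing 29.75 keV, with 2447
linkages at 10 bp and 905 at 5 bp. The report contains (values the
commands above actually print):

```
y_ssb  1.903e-10   y_dsb      1.324e-11
y_bd   2.474e-10   y_cbd      2.238e-11
                   y_cbd_star 1.410e-11
ratios: bd_ssb = 1.3, dsb_ssb = 0.0696, cbd_bd = 0.0905, cdsb_dsb = 12.75
```

`y_*` are yields in Gy⁻¹Da⁻¹: at this event density about 7% of
strand-break damage is double-stranded (`dsb_ssb`), 12.8% of DSBs carry
extra strand breaks (`cdsb_dsb`, per the DSB/DSB+/DSB++ split), and of
the complex base damage only `y_cbd_star` ≈ 63% survives the
probe-size detection loss. `bd_ssb = 1.3` is exact by construction —
the defining property of the base-damage coefficients. The class table
(`classes.tsv`) shows each scheme's site counts, fractions and split
yields, e.g. 74% of DSB sites are simple (N_cl < 11) and 26% carry one
base damage. With `--eta 0.9` the detected cBD yield drops to
0.81 · y_cbd = 1.813e-11.

The same pipeline runs on real track-structure output once exported to
the event TSV (`track_id  x_nm  y_nm  z_nm  kind  edep_eV`, kind
`ION`/`EXC`, one inelastic event per row).

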