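# icpkit

Molecular karyotyping of products of conception (POC) from interphase
nuclei, implemented as a testable software pipeline.

Roughly half of first-trimester miscarriages carry a chromosome abnormality
— trisomy, monosomy, triploidy/tetraploidy, or an (un)balanced
rearrangement — but conventional cytogenetics of POC tissue fails to
culture in 15–20% of attempts and often returns only maternal cells.
Interphase chromosome profiling (ICP) sidesteps cell culture: each
chromosome is interrogated in a separate multi-color FISH hybridization of
non-dividing nuclei, and a genome-wide karyotype is assembled from the
per-chromosome signal patterns. `icpkit` models that workflow end to end
for cytogeneticists and method developers: the probe panels, a nucleus-level
spot simulator, the per-cell signal extraction, the rule-based caller, and
the `icp.` nomenclature.

## The method

**Panels.** The Standard Resolution panel runs 23 hybridizations: every
non-acrocentric autosome and the X carry a green subtelomeric p (pter),
yellow pericentromeric (cen) and red subtelomeric q (qter) probe;
acrocentrics (13, 14, 15, 21, 22) have no p-arm probe; the Y is marked by
an aqua Yp probe and shares one hybridization with the X. A separate
Acrocentric mix places one pericentromeric probe per acrocentric in five
distinct colors to detect Robertsonian translocations as fused two-color
signals.

**Scoring rules.** A minimum of 20 interphase cells is analyzed per
chromosome. The copy number of each probe is the modal per-cell count of
distinct signal clusters of its color; a second cell population is reported
(mosaicism) only when seen in at least 4 cells **and** at least 20% of
cells. A juxtaposition of two signals — spots within the fusion radius,
merged by single-linkage clustering — is abnormal only in **strictly more
than 20%** of nuclei (4/20 is still normal); Robertsonian derivatives show
it in essentially every cell. Terminal deletions read as a missing pter or
qter signal; unbalanced derivatives pair a terminal loss on one chromosome
with a displaced extra terminal on another, `der(B)t(A;B)`; balanced
translocations show normal counts with a terminal signal displaced away
from its own pericentromeric anchor on both partners.

**Nomenclature.** Results carry the `icp.` prefix and a `[cpN]` composite
suffix (the call is assembled from N separately analyzed cells), e.g.
`icp.46,XY,der(14;21)(q10;q10),+21[cp20]` for a Robertsonian translocation
trisomy 21, or `icp.92,XXXX/46,XX` for a mosaic tetraploid.

## Worked example

Simulate a male Robertsonian translocation trisomy 14 and call it back:

```sh
$ cat scenario.json
{"populations": [{"karyotype": "46,XY,der(13;14)(q10;q10),+14", "fraction": 1.0}],
 "config": {"n_cells": 20, "seed": 7}}

$ icpkit simulate scenario.json --out sim
wrote 24 spot tables to sim

$ icpkit call sim --out report.json
icp.46,XY,der(13;14)(q10;q10),+14[cp20]

$ icpkit report report.json
result      : icp.46,XY,der(13;14)(q10;q10),+14[cp20]
ploidy      : DIPLOID   sex: XY
population  : 46,XY,der(13;14)(q10;q10),+14
cells       : min 20 per hybridization
```

The 24 spot tables are the 23 standard hybridizations plus the acrocentric
mix. On the mix, the derivative appears as a consistently fused
yellow(13)+green(14) signal with three green signals in total; the caller
classifies the fusion as abnormal (present in >20% of nuclei), reads the
extra chromosome 14 from the participant totals, and folds the trisomy
into the derivative rather than reporting `+14` twice — hence 46
chromosomes, not 47.

The same loop is available in Python:

```python
import icpkit as k

panel = k.build_full_panel()
tables = k.simulate_case("47,XX,+16", panel, k.SimulationConfig(seed=1))
call = k.karyotype_case(tables, panel, n_cells=20)
print(call.icp_string)          # icp.47,XX,+16[cp20]
```

The package also ships the four published validation tables (83 initial
plus 291 clinical specimens) as TSV fixtures; `icpkit validate-tables`
re-classifies every printed result string and round-trips each of the 41
concurrent-cytogenetics clinical karyotypes through simulation and
re-calling.

## Documentation

See `docs/methods.md` for the nucleus model, the calling rules and their
thresholds, numerical choices, and known limitations.
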