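"""Published WT-box census of the Arabidopsis thaliana genome.

Reference inputs for re-analysis without the TAIR10 / Araport11 sequence
databases: the published occurrence counts of the 16 WT-boxes NGACTTTN in
the 500-bp upstream regions of all 33,323 nuclear loci and genome-wide, the
corresponding genome-wide per-nucleotide frequencies, and the
composition-expected frequencies derived from the upstream GC content of
32.62%.  These are inputs to the statistical machinery (the census was
produced by PatMatch searches of those databases), not outputs of this
package.
"""

from __future__ import annotations

#: the degenerate WT-box and its concrete variants
WT_BOX_IUPAC = "NGACTTTN"
WT_BOX_CORE = "GACTTT"
#: the classic WRKY binding site, TTGACC or TTGACT
W_BOX_IUPAC = "TTGACY"

#: all 16 concrete WT-boxes xGACTTTy, x,y in {A,C,G,T}
ALL_WT_BOXES = tuple(
    f"{x}{WT_BOX_CORE}{y}" for x in "ACGT" for y in "ACGT"
)

#: GC fraction of the 500-bp upstream regions of the 33,323 nuclear loci
UPSTREAM_GC_FRACTION = 0.3262
#: number of loci and the nucleotide denominator (33,323 x 500)
N_UPSTREAM_LOCI = 33_323
UPSTREAM_REGION_NT = N_UPSTREAM_LOCI * 500  # 16,661,500

#: per WT-box: (upstream count, genome-wide count,
#:             genome-wide frequency, composition-expected frequency)
WT_BOX_CENSUS: dict[str, tuple[int, int, float, float]] = {
    "AGACTTTA": (969, 7_633, 5.6261e-05, 3.88968e-05),
    "AGACTTTC": (563, 5_432, 4.0038e-05, 1.88307e-05),
    "AGACTTTG": (893, 8_106, 5.9748e-05, 1.88307e-05),
    "AGACTTTT": (1_697, 10_639, 7.8418e-05, 3.88968e-05),
    "CGACTTTA": (327, 2_525, 1.8611e-05, 1.88307e-05),
    "CGACTTTC": (239, 2_121, 1.5633e-05, 9.11633e-06),
    "CGACTTTG": (379, 3_259, 2.4021e-05, 9.11633e-06),
    "CGACTTTT": (652, 3_683, 2.7147e-05, 1.88307e-05),
    "GGACTTTA": (348, 2_790, 2.0565e-05, 1.88307e-05),
    "GGACTTTC": (255, 2_938, 2.1655e-05, 9.11633e-06),
    "GGACTTTG": (428, 4_440, 3.2726e-05, 9.11633e-06),
    "GGACTTTT": (660, 4_387, 3.2336e-05, 1.88307e-05),
    "TGACTTTA": (1_069, 7_216, 5.3188e-05, 3.88968e-05),
    "TGACTTTC": (717, 5_519, 4.0680e-05, 1.88307e-05),
    "TGACTTTG": (1_155, 9_374, 6.9094e-05, 1.88307e-05),
    "TGACTTTT": (2_319, 12_436, 9.1663e-05, 3.88968e-05),
}

#: published sizes of the WRKY ChIP target-gene lists intersected with the
#: WT-box-present / W-box-absent promoter set
WRKY_TARGET_LIST_SIZES = {"WRKY18": 1_290, "WRKY33": 1_140, "WRKY40": 1_478}
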