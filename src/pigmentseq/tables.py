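"""Printed expression tables from the zebrafish pigment-cell study.

These are the published per-gene mean RPKM values (and, where printed,
Student's t-test p-values) for melanocytes, iridophores, retinal pigmented
epithelium (RPE), and pooled 3 dpf whole embryos.  They serve as small,
exactly-known expression profiles: each published table was produced by one
of the enrichment presets in :mod:`pigmentseq.classify`, so re-applying the
preset to the printed values must retain every row.

Loader functions return profiles in the canonical in-memory layout (see
:mod:`pigmentseq.io`): columns ``gene``, ``melanocyte``, ``rpe``,
``iridophore``, ``embryo`` plus any p-value columns present.
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = [
    "control_genes",
    "shared_identity_genes",
    "mel_rpe_genes",
    "mel_irid_genes",
    "irid_enriched_genes",
    "guanine_pathway_profile",
    "guanine_pathway_groups",
]

# Candidate control genes (RPKM and pairwise t-test p-values; no embryo column
# was printed for these).
_CONTROL = """\
gene\tmelanocyte\trpe\tiridophore\tp_mel_rpe\tp_mel_irid\tp_rpe_irid
gch2\t54.25\t9.81\t1.58\t0.007\t0.002\t0.113
mlphb\t187.84\t7.96\t1.39\t0.004\t0.003\t0.251
kita\t3.78\t0.39\t0.02\t0.019\t0.011\t0.076
pmela\t15177.25\t4244.20\t148.90\t0.051\t0.011\t0.031
dct\t14134.12\t6406.98\t402.47\t0.025\t0.000\t0.028
tyrp1b\t12354.09\t3769.95\t200.99\t0.026\t0.004\t0.009
atic\t7.60\t9.63\t467.16\t0.664\t0.010\t0.010
ednrb1\t4.44\t1.72\t28.63\t0.110\t0.018\t0.013
ltk\t0.02\t0.20\t4.02\t0.138\t0.002\t0.002
sox10\t7.57\t1.76\t13.00\t0.010\t0.078\t0.005
foxd3\t3.03\t0.35\t6.41\t0.012\t0.237\t0.063
snai2\t4.26\t0.79\t4.08\t0.016\t0.904\t0.020
pax6a\t10.04\t47.48\t0.73\t0.098\t0.004\t0.055
nr2e1\t0.75\t2.41\t0.05\t0.189\t0.041\t0.086
myo7ab\t1.89\t3.32\t0.15\t0.050\t0.001\t0.003
"""

# Genes co-enriched in all three pigment cell types (shared pigment-cell
# identity set: within 2-fold of each other, >= 4 RPKM, >= 100-fold over
# whole embryo).
_SHARED_IDENTITY = """\
gene\tmelanocyte\trpe\tiridophore\tembryo
rpl26\t22354.26\t19692.74\t23528.06\t87.23
rps17\t12677.82\t10420.73\t16940.17\t59.88
rps2\t12516.82\t9306.57\t12379.31\t89.39
rpl27a\t6506.97\t5852.65\t8537.27\t48.50
slc45a2\t4415.88\t2376.16\t2801.48\t0.20
rps26l\t2338.29\t2362.00\t2596.78\t23.08
ppp1r21\t263.06\t227.24\t202.38\t1.77
crfb5\t237.93\t329.44\t301.82\t1.19
LOC100535047\t217.00\t212.13\t135.05\t0.40
dhdh\t201.46\t185.72\t161.64\t1.52
cyhr1\t150.55\t157.36\t138.95\t0.87
igf2bp2b\t133.81\t97.93\t128.56\t0.75
ghitm\t133.71\t119.78\t162.37\t0.99
her9\t126.24\t85.17\t120.90\t0.71
fam168a\t89.26\t78.21\t73.66\t0.44
comtb\t81.11\t55.05\t70.61\t0.32
fkbp3\t75.26\t59.48\t79.66\t0.01
mtbl\t65.94\t36.58\t48.31\t0.32
pard3b\t53.47\t62.57\t46.53\t0.38
hbp1\t41.93\t50.61\t52.08\t0.12
zgc:158345\t31.67\t43.92\t59.38\t0.31
ccdc85al\t31.26\t34.99\t40.96\t0.13
grma\t17.17\t18.26\t28.83\t0.10
mbd2\t16.57\t16.03\t16.31\t0.13
triobpl\t14.28\t16.86\t12.85\t0.01
rnd2\t14.23\t10.66\t12.26\t0.00
LOC100334991\t10.17\t7.87\t10.08\t0.03
zgc:136564\t5.94\t9.00\t5.30\t0.04
"""

# The 38 most highly expressed genes co-enriched in melanocytes and RPE
# (each >= 10-fold over iridophores and whole embryo, minimum 10 RPKM).
# kif21al appears twice in the published list (two distinct records).
_MEL_RPE = """\
gene\tmelanocyte\trpe\tiridophore\tembryo
pmela\t15177.25\t4244.20\t148.90\t0.57
dct\t14134.12\t6406.98\t402.47\t0.65
tyrp1b\t12354.09\t3769.95\t200.99\t1.13
tyrp1\t2546.87\t1474.07\t71.46\t0.03
rlbp1b\t1181.62\t1212.86\t48.19\t0.26
mitfa\t1122.44\t448.53\t16.22\t0.00
pah\t1081.84\t485.25\t35.79\t23.60
stra6\t703.09\t539.15\t32.81\t3.00
rgra\t300.56\t504.34\t27.16\t0.21
msnb\t254.08\t217.35\t11.10\t0.45
fam213ab\t217.86\t160.16\t12.32\t0.28
rbp1a\t148.55\t137.02\t8.74\t1.79
slc24a4a\t141.08\t89.64\t7.63\t1.26
zgc:114181\t122.41\t128.26\t6.71\t0.58
mab21l2\t120.20\t176.48\t2.98\t0.82
LOC100004225\t105.78\t52.37\t3.46\t1.32
lratl\t105.09\t96.40\t3.52\t0.39
oca2\t102.56\t56.96\t1.63\t0.07
kif21al\t96.64\t104.62\t4.16\t0.82
dhrs11al\t95.71\t130.88\t6.86\t8.45
cadm3\t87.46\t116.23\t4.88\t0.12
cdh2\t86.69\t99.72\t6.17\t1.10
slc24a5\t83.81\t34.68\t1.56\t0.00
s1pr1\t83.14\t74.37\t4.78\t1.20
ctgf\t62.15\t62.19\t4.20\t0.32
fads6\t49.52\t84.55\t2.76\t0.08
foxp4\t39.96\t84.03\t1.78\t0.25
foxg1b\t39.71\t64.02\t2.38\t0.10
kif21al\t37.47\t58.20\t3.21\t0.37
abcg2d\t34.72\t48.81\t1.58\t0.00
LOC100149324\t33.08\t31.15\t1.55\t0.14
efcab4b\t30.89\t38.65\t1.71\t0.00
col11a1a\t27.39\t27.11\t1.22\t0.75
rdh13\t24.30\t31.04\t0.81\t0.00
cam4l\t23.38\t37.54\t1.34\t0.29
srcrb4l\t21.14\t20.88\t1.18\t0.80
col4a5\t20.86\t29.39\t1.69\t0.49
dao.2\t20.27\t22.39\t1.23\t1.39
"""

# Genes co-enriched in melanocytes and iridophores (each >= 5-fold over RPE
# and >= 10-fold over whole embryo).
_MEL_IRID = """\
gene\tmelanocyte\tiridophore\trpe\tembryo
syngr2l\t86.584\t50.745\t5.728\t1.471
tuba8l3\t78.779\t132.465\t11.725\t0.397
pcdh10a\t59.639\t54.800\t5.143\t0.423
crestin\t16.922\t25.646\t2.214\t0.145
LOC559216\t14.652\t27.212\t1.350\t0.689
si:dkey-72l14.7\t11.657\t40.247\t1.004\t0.000
cdk15\t8.492\t6.475\t0.291\t0.112
emp3l\t6.859\t17.644\t0.293\t0.046
lamb1b\t5.486\t6.138\t0.630\t0.427
zgc:158328\t4.355\t8.553\t0.776\t0.004
opn5\t3.824\t1.796\t0.193\t0.000
ppfia2\t3.521\t3.859\t0.443\t0.037
rab27bl\t3.263\t13.331\t0.278\t0.118
mc1r\t2.182\t3.958\t0.076\t0.000
birc7\t1.818\t2.960\t0.233\t0.000
"""

# Iridophore-enriched genes (>= 30-fold over melanocytes and RPE, >= 100-fold
# over whole embryo).
_IRID = """\
gene\tiridophore\tmelanocyte\trpe\tembryo
ifi30l\t2138.17\t6.55\t27.16\t1.23
fhl3\t1003.29\t4.64\t20.97\t1.12
slc23l\t592.05\t10.64\t9.70\t1.19
gpnmb\t423.58\t1.02\t5.28\t1.70
LOC100538040\t396.38\t1.52\t9.30\t1.85
LOC100334697\t330.19\t1.06\t4.78\t0.09
tpd52l1\t252.61\t5.69\t7.75\t1.02
LOC100535932\t221.28\t0.98\t4.64\t0.18
pltp\t145.30\t1.07\t2.02\t0.02
LOC795494\t127.94\t0.43\t2.17\t0.11
LOC100330987\t99.01\t0.56\t1.80\t0.01
zgc:77375\t94.86\t0.44\t2.24\t0.01
slc25a38a\t94.77\t1.10\t1.63\t0.46
LOC100534970\t81.87\t0.65\t2.48\t0.18
tmem179bl\t79.07\t0.32\t0.66\t0.14
fkbp15\t32.47\t0.55\t0.51\t0.31
pcolcel\t30.46\t0.31\t0.22\t0.00
si:ch211-38m6.6\t28.42\t0.12\t0.23\t0.00
tagln3b\t24.88\t0.13\t0.74\t0.06
alx4b\t24.81\t0.10\t0.24\t0.08
hsf5\t21.07\t0.05\t0.20\t0.00
osbpl10\t18.67\t0.26\t0.55\t0.08
si:dkey-225f23.4\t14.27\t0.14\t0.13\t0.00
zgc:112054\t12.99\t0.34\t0.40\t0.00
slc52a3\t12.73\t0.03\t0.12\t0.12
cart1\t9.87\t0.19\t0.28\t0.00
myadm\t7.81\t0.14\t0.23\t0.00
znf831\t7.04\t0.09\t0.10\t0.06
si:ch211-14k19.8\t5.80\t0.06\t0.09\t0.00
nfascl\t5.27\t0.07\t0.11\t0.00
"""

# Guanine-synthesis-related enzymes in iridophores, with t-test p-values for
# iridophore-vs-melanocyte and iridophore-vs-RPE.
_GUANINE = """\
gene\tiridophore\tmelanocyte\trpe\tembryo\tp_irid_mel\tp_irid_rpe
slc2a15a\t48.55\t0.16\t0.73\t0.28\t7.66E-03\t7.89E-03
pgm2\t34.00\t0.54\t0.73\t1.24\t4.64E-03\t4.68E-03
dera\t3.67\t0.98\t0.39\t2.76\t3.40E-04\t1.55E-04
pfkp\t12.25\t0.63\t1.28\t2.42\t1.31E-02\t1.53E-02
aldoca\t6.22\t0.04\t0.00\t0.83\t2.50E-03\t2.45E-03
gapdhs\t1605.92\t191.73\t163.31\t9.03\t1.92E-02\t1.79E-02
pgk1\t281.34\t146.41\t125.46\t38.36\t9.05E-03\t7.22E-03
pgam1a\t587.26\t216.58\t158.84\t32.46\t1.13E-03\t4.02E-04
eno3\t1503.93\t215.46\t307.89\t100.27\t4.30E-08\t4.09E-05
pkm2a\t371.83\t115.96\t97.94\t24.94\t4.52E-04\t2.83E-04
ldhba\t440.62\t74.53\t44.46\t72.72\t2.70E-04\t2.85E-04
phgdh\t1538.41\t371.96\t175.60\t8.25\t4.21E-03\t2.22E-03
psat1\t160.85\t7.03\t11.92\t7.62\t4.68E-03\t3.85E-03
psph\t2602.05\t146.30\t102.78\t1.36\t1.53E-03\t1.38E-03
shmt2\t86.02\t5.37\t5.92\t2.83\t9.83E-03\t9.50E-03
mthfd1\t177.66\t7.98\t8.41\t13.99\t2.71E-02\t2.72E-02
fh\t562.28\t150.18\t109.27\t8.65\t2.53E-02\t1.81E-02
mdh1a\t3948.05\t388.29\t432.95\t27.33\t2.55E-05\t1.48E-05
pck2\t1.44\t0.10\t0.01\t6.09\t1.05E-02\t8.50E-03
aclya\t106.57\t42.29\t39.30\t8.19\t2.49E-03\t1.72E-03
rpia\t11.66\t2.49\t2.24\t6.52\t4.70E-03\t3.89E-03
prpsap1\t95.27\t35.48\t24.12\t3.13\t3.13E-03\t1.88E-03
ppat\t49.23\t2.49\t3.72\t7.89\t4.22E-03\t4.26E-03
gart\t167.66\t6.41\t4.29\t3.46\t6.01E-03\t5.72E-03
pfas\t34.59\t0.53\t0.56\t4.53\t1.52E-03\t1.51E-03
paics\t1465.37\t57.12\t55.35\t11.68\t3.63E-03\t3.50E-03
adsl\t805.77\t46.06\t36.43\t12.45\t2.69E-03\t2.38E-03
atic\t467.16\t7.60\t9.63\t18.34\t1.01E-02\t1.02E-02
impdh1b\t816.19\t11.45\t21.98\t1.06\t1.30E-03\t1.21E-03
gmps\t102.41\t3.86\t5.14\t6.35\t1.15E-03\t1.02E-03
prtfdc1\t309.88\t1.56\t3.10\t0.00\t1.39E-03\t1.39E-03
hprt1l\t21.31\t0.25\t1.13\t15.99\t7.28E-04\t6.03E-04
adssl\t0.73\t1.04\t1.75\t6.82\t2.61E-01\t1.08E-01
ak1\t87.12\t228.27\t149.74\t40.66\t4.24E-03\t1.75E-01
"""

# Pathway membership for the guanine-synthesis report, in table order.
_GUANINE_GROUPS: dict[str, tuple[str, ...]] = {
    "glucose_transport": ("slc2a15a",),
    "glycolysis": (
        "pgm2", "dera", "pfkp", "aldoca", "gapdhs",
        "pgk1", "pgam1a", "eno3", "pkm2a", "ldhba",
    ),
    "serine_glycine": ("phgdh", "psat1", "psph", "shmt2", "mthfd1"),
    "citrate_cycle": ("fh", "mdh1a", "pck2", "aclya"),
    "pentose_phosphate": ("rpia", "prpsap1"),
    "purine_de_novo": ("ppat", "gart", "pfas", "paics", "adsl", "atic"),
    "guanine_branch": ("impdh1b", "gmps"),
    "purine_salvage": ("prtfdc1", "hprt1l"),
    "adenine_branch": ("adssl", "ak1"),
}


def _load(text: str) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(text), sep="\t")


def control_genes() -> pd.DataFrame:
    """Candidate control genes with pairwise t-test p-values (15 genes)."""
    return _load(_CONTROL)


def shared_identity_genes() -> pd.DataFrame:
    """The 28 genes co-enriched in all three pigment cell types."""
    return _load(_SHARED_IDENTITY)


def mel_rpe_genes() -> pd.DataFrame:
    """The 38 most highly expressed melanocyte+RPE co-enriched genes."""
    return _load(_MEL_RPE)


def mel_irid_genes() -> pd.DataFrame:
    """The 15 melanocyte+iridophore co-enriched genes."""
    return _load(_MEL_IRID)


def irid_enriched_genes() -> pd.DataFrame:
    """The 30 stringently iridophore-enriched genes."""
    return _load(_IRID)


def guanine_pathway_profile() -> pd.DataFrame:
    """Guanine-synthesis enzymes: RPKM plus iridophore-vs-mel/RPE p-values."""
    return _load(_GUANINE)


def guanine_pathway_groups() -> dict[str, tuple[str, ...]]:
    """Pathway label -> gene ids for the guanine-synthesis report."""
    return {k: tuple(v) for k, v in _GUANINE_GROUPS.items()}
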