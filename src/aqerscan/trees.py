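"""Reference phylogeny used throughout the package.

``GREAT_APE_TREE_NEWICK`` is a published 20-haplotype great-ape phylogeny
(8 human haplotypes plus primary/alternate haplotypes of chimpanzee,
bonobo, gorilla, Sumatran and Bornean orangutan, and siamang gibbon) with
named internal nodes and Jukes-Cantor branch lengths estimated from
fourfold-degenerate coding sites.  Key internal nodes: ``HUMANanc`` (most
recent common ancestor of the sampled human haplotypes), ``hcaT2T``
(human-chimpanzee ancestor), ``hgaT2T`` (human-gorilla ancestor).
"""

GREAT_APE_TREE_NEWICK = (
    "((((((humanT2T:0.000435156,(HG002mat:0.00102161,HG002pat:0.000477313)"
    "HG002anc:0.000673322)EURanc:0.000910852,(Han1:0.000470491,"
    "((CN1mat:0.000681227,CN1pat:0.000424938)CN1anc:0.000913969,"
    "(YAOmat:0.000565216,YAOpat:0.00100586)YAOanc:0.000811958)"
    "CHNdipanc:0.000659018)CHNanc:0.000573093)HUMANanc:0.00606109,"
    "((chimpT2Tpri:0.000514677,chimpT2Talt:0.000464187)chimpT2Tanc:0.00153813,"
    "(bonoboT2Tpri:0.000575461,bonoboT2Talt:0.000886081)bonoboT2Tanc:0.00163245)"
    "cbaT2T:0.00445874)hcaT2T:0.00227545,"
    "(gorillaT2Tpri:0.000928497,gorillaT2Talt:0.00102789)gorillaT2Tanc:0.00856474)"
    "hgaT2T:0.0110735,((orangutanT2Tpri:0.00115159,orangutanT2Talt:0.00123407)"
    "orangutanT2Tanc:0.000658367,(borangutanT2Tpri:0.000978752,"
    "borangutanT2Talt:0.00100708)borangutanT2Tanc:0.000857815)obaT2T:0.0176608)"
    "hoaT2T:0.0116854,(gibbonT2Tpri:0.000825439,gibbonT2Talt:0.00102365)"
    "gibbonT2Tanc:0.0116854)hgiaT2T;"
)


def great_ape_tree():
    """The reference phylogeny as a :class:`~aqerscan.phylo_model.PhyloTree`."""
    from .phylo_model import parse_newick

    return parse_newick(GREAT_APE_TREE_NEWICK)
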