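"""Build a parsimony clade tree from a handful of variant profiles.

Six haplotypes over the W motif region: the builder founds clades on the
most widely shared stable variants, leaves the recurrent control-region
site 185 on separate branches (three independent hits, as a hotspot
should be), and reports shared-derived subclades.
"""

from mitophylo import VariantProfile, build_tree, detect_subclades, homoplasy_scan
from mitophylo.tree import write_newick

PROFILES = {
    "s1": "1406 8251 16292 185",
    "s2": "1406 8251 16292",
    "s3": "4093 8614 16325 8251 16292 185",
    "s4": "4093 8614 16325 8251 16292",
    "s5": "8251 16292 185",
    "s6": "8251 16292",
}


def main() -> None:
    profiles = [VariantProfile.from_tokens(s, t) for s, t in PROFILES.items()]
    tree = build_tree(profiles)
    print(write_newick(tree))
    print(f"\ntotal mutations on edges: {tree.total_mutations()}")
    for node, muts in detect_subclades(tree, min_tips=2):
        tips = ",".join(t.name for t in node.tips())
        print(f"subclade [{tips}] defined by {' '.join(v.render() for v in muts)}")
    for rep in homoplasy_scan(tree):
        print(f"recurrent: position {rep.position} hit on {rep.occurrences} branches")


if __name__ == "__main__":
    main()
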