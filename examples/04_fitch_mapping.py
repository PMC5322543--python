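"""Map binding-site presence/absence onto a gene-family tree.

Mirrors the jacalin-family analysis: three tandem duplicates form a clade
in which two genes are targeted by one miRNA family and the middle gene
is not, plus an outgroup pair targeted by a second family. Fitch
parsimony counts the minimal gains/losses per family.
"""

from mirdiverge import load_tree, map_family_tree

tree = load_tree("(((AT5G49850,AT5G49860),AT5G49870),(AT5G28520,AT5G38550));")
target_sets = {
    "AT5G49850": {"ath-miR846"},
    "AT5G49860": set(),
    "AT5G49870": {"ath-miR846"},
    "AT5G28520": {"ath-miR842", "ath-miR846"},
    "AT5G38550": {"ath-miR842"},
}

report = map_family_tree(tree, target_sets)
print(report.table.to_string(index=False))

# Each row gives the minimal number of gain/loss events explaining the
# presence/absence pattern of one miRNA family across the leaves; two or
# more events signal the kind of dynamic site turnover seen in jacalins.
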