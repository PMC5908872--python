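"""Published summary figures from the original analysis of GEO series
GSE112474 (canine lymphomas and lymphoid cell lines vs. control lymph
nodes). These printed counts are inputs for arithmetic-identity checks —
the full dataset is not re-analyzed here, but the relations between the
published numbers are fully determined by the pipeline's definitions
(detection rate, filter retention, consistency-set sums, core partition,
net expression, SOM band fractions) and must recompute exactly.
"""

REPORTED = {
    # annotation and two-stage filter, per biotype
    "protein_coding_annotated": 19_856,
    "protein_coding_detected": 17_950,
    "protein_coding_retained": 10_771,
    "miRNA_annotated": 846,
    "miRNA_detected": 401,
    "miRNA_retained": 246,
    "lncRNA_annotated": 8_124,
    "lncRNA_detected": 4_729,
    "lncRNA_low_expressed": 1_889,
    "lncRNA_retained": 2_840,
    # library structure
    "n_libraries": 37,
    # DEG totals
    "degs_total": 5_712,
    "degs_lymphomas": 1_703,
    "degs_cell_lines": 5_443,
    # B-cell vs probable T-cell lymphoma overlap
    "shared_b_probt": 439,
    "shared_b_probt_up": 227,
    "shared_b_probt_down": 206,
    # lymphoma genes consistent across all cell lines
    "consistent_total": 1_362,
    "consistent_up": 481,
    "consistent_down": 881,
    # all-group core
    "core_total": 166,
    "core_up": 78,
    "core_down": 86,
    "core_discordant": 2,
    # pathway scoring
    "pathways_downloaded": 309,
    "pathways_scored": 257,
    "ne_most_negative_n_down": 22,     # "tuberculosis" in OSW
    "ne_most_negative_n_detected": 39,
    "ne_most_positive_n_up": 17,       # "DNA replication" in CLBL-1
    "ne_most_positive_n_down": 1,
    "ne_most_positive_n_detected": 32,
    # SOM unit bands
    "som_near_zero_pathways": 72,
    "som_negative_pathways": 94,
    "som_positive_pathways": 18,
    # PCA of DEG expression
    "pc1_variance_percent": 15.0,
    "pc2_variance_percent": 10.0,
}
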