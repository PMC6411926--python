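#!/bin/sh
# Example: genome-wide peak-overlap analysis with `cspfit overlap`.
#
# This script documents how to compare a reader-protein's ChIP-seq peaks
# with histone-mark and chromatin-accessibility peaks using the maxgap
# rule (overlap = within 150 bp on a compatible strand). It needs BED
# files downloaded from a repository such as ENCODE or GEO and therefore
# is NOT run by the test suite; substitute your own accessions/paths.
#
#   reader.bed      ChIP-seq peaks for the reader protein of interest
#   h3k27me3.bed    repressive-mark peaks in the same cell line
#   h3k9me3.bed     heterochromatin-mark peaks
#   dnase.bed       DNase hypersensitive sites
#
# Peak calls from different pipelines should be against the same genome
# build; lift over first if they are not.

set -eu

# fraction of reader peaks within 150 bp of a repressive-mark peak
cspfit overlap --query reader.bed --subject h3k27me3.bed --max-gap 150

# contrast with a different mark
cspfit overlap --query reader.bed --subject h3k9me3.bed --max-gap 150

# three-way Venn counts (reader x repressive mark x accessibility),
# anchored per set; BED3 inputs are treated as unstranded wildcards
cspfit overlap --query reader.bed --subject h3k27me3.bed --third dnase.bed \
    --max-gap 150 --out overlap_results/
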