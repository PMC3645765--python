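#categories: inflammation,diabetes
# Synthetic demonstration annotation: 19 miRNAs with inflammation/diabetes
# labels for exercising the category-tally report. Assignments are
# illustrative placeholders, not a curated pathway resource.
miR-21	inflammation
miR-101	inflammation
miR-182	inflammation
miR-183	inflammation
miR-200b	inflammation
miR-200c	inflammation
miR-141	inflammation
miR-191	inflammation
miR-30a	diabetes
miR-103	diabetes
miR-143	diabetes
miR-27a	diabetes
miR-27b	diabetes
miR-148a	diabetes
miR-378	diabetes
miR-365	diabetes
miR-146a	diabetes
miR-199a	inflammation
miR-199a	diabetes
miR-15a	inflammation
miR-15a	diabetes
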