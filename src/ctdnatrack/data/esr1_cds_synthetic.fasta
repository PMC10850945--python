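>NM_000125.4 ESR1 coding sequence (synthetic stand-in: anchor codons match published variant annotations; filler codons arbitrary)
ATGCTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACCATAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGAG
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCTTTGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGTCTAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACCTCTATGATATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACAGAAACCTCATGGCT
GAACTGAGCAAGGTGGACCCTATCACCTTCCAGGGCCACTGGTACTGA
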