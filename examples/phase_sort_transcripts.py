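"""Sort auxin-responsive transcripts by cell-cycle peak phase.

Builds a small differential-expression table, keeps transcripts with
|log2 fold change| > 1.5 and adjusted P <= 0.1, and partitions them by
their annotated expression peak (G1, S/M/C, or noncyclical).
"""

import pandas as pd

from pullcall import DETable, PhaseAnnotation, phase_sort

de = DETable(
    frame=pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3", "t4", "t5", "t6"],
            "log2_change": [2.1, -1.8, 1.5, 0.4, -2.6, 3.0],
            "adjusted_p": [0.01, 0.02, 0.01, 0.001, 0.04, 0.50],
        }
    )
)
annotation = PhaseAnnotation(
    phases=pd.Series(
        {"t1": "G1", "t2": "G1", "t3": "SMC", "t4": "SMC", "t5": "NONCYCLICAL"}
    )
)

groups = phase_sort(de, annotation, lfc_threshold=1.5, padj_threshold=0.1)
for phase, members in groups.items():
    print(f"{phase:12s} {len(members)} transcript(s): {', '.join(members) or '-'}")
# t3 sits exactly at 1.5 and is excluded (the cutoff is strict); t6 fails
# the adjusted-P filter; t4 is below the fold-change cutoff
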