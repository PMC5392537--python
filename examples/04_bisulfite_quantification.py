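"""Quantify CpG methylation from simulated bisulfite amplicon reads.

Simulates paired-end MiSeq-style reads for two markers of the 16-assay
panel (true methylation 70% and 20%, bisulfite conversion 98%), assigns
reads to amplicons, counts C/T at each CpG, and corrects for conversion
failure using the built-in non-CpG cytosine controls.
"""

from epiage import default_panel, quantify, simulate_reads

panel = default_panel()
batch = simulate_reads(
    panel, {"cg19761273": 0.70, "cg22736354": 0.20},
    n_fragments=2000, conversion_rate=0.98, seq_error_rate=0.002, seed=7,
)
print(f"simulated {len(batch)} paired-end reads")

calls = quantify(batch, panel, min_reads=1000)
targets = calls[calls["is_target"]]
cols = ["marker", "offset", "c_count", "t_count", "coverage",
        "conversion_rate", "raw_beta", "corrected_beta", "pass_coverage"]
print(targets[cols].round(4).to_string(index=False))

# raw_beta = C/(C+T) at the CpG; the conversion rate estimated from control
# cytosines inflates raw_beta by (1-rate)(1-m), which corrected_beta undoes.
# Markers under 1000 reads would be flagged pass_coverage=False and excluded.
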