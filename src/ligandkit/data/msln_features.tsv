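# Region annotations for the MSLN precursor (AAV87530.1 numbering, 1-based
# inclusive). Moiety boundaries are derived from the furin site RPRFRR at
# 290-295 (cleavage after R295); leader and GPI-signal extents are
# approximate annotations for display and per-region coverage summaries.
kind	start	end	label
leader	1	33	leader
furin_site	290	295	furin_site
domain_boundary	34	295	MPF
domain_boundary	296	622	MSLN
gpi_signal	599	622	gpi_signal
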