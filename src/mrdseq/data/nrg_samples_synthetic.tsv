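# Synthetic reconstruction: the non-recurrence control cohort is reported only in
# aggregate (9 patients, 12 samples: 5 BM + 7 PB, all MRD-negative by NGS at a
# well-engrafted time point); the per-sample patient assignment below is invented.
patient_id	source	days_before_relapse	group	str_status	ngs_status	mfc_status
NRG01	BM		NRG	Negative	Negative	NotPerformed
NRG01	PB		NRG	Negative	Negative	NotPerformed
NRG02	BM		NRG	Negative	Negative	NotPerformed
NRG02	PB		NRG	Negative	Negative	NotPerformed
NRG03	BM		NRG	Negative	Negative	Negative
NRG03	PB		NRG	Negative	Negative	NotPerformed
NRG04	BM		NRG	Negative	Negative	NotPerformed
NRG05	BM		NRG	Negative	Negative	NotPerformed
NRG06	PB		NRG	Negative	Negative	NotPerformed
NRG07	PB		NRG	Negative	Negative	Negative
NRG08	PB		NRG	Negative	Negative	NotPerformed
NRG09	PB		NRG	Negative	Negative	NotPerformed
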