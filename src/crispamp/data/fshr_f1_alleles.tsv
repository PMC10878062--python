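sample_id	sequence
269	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAACTTCACCAACCTCCTGCAGCTCACTGCCAT
271	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCTTCACCAACCTCCTGCAGCTCACTGCCAT
280	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
280	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAACTTCACCAACCTCCTGCAGCTCACTGCCAT
283	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCTTACATGCAGCTCACTGCCAT
287	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGATGTGCCTCCTGCAGAGTGTTTCCCCGATGTGCCTCCTGCAGCTCACTGCCAT
292	GAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGGGGAAACGCACTTCACCAACCTCCTGCAGCTCACTGCCAT
294	GGAGTTCAAACAGACGCACATCAGAGTGTTTCAACCTCCTGCAGCTCACTGCCAT
317	GGAGTTCAAACAGACGCACATCAGAGTGTTTCAACCTCCTGCAGCTCACTGCCAT
317	GGAGTTCAAACAGACGCACATCAGAGTGTTTCACCAACCTCCTGCAGCTCACTGCCAT
322	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
322	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGGGGAAACGCACTTCACCAACCTCCTGCAGCTCACTGCCAT
324	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCACATCAGAGTGTTTCTTCACCAACCTCCTGCAGCTCACTGCCAT
342	GGAGTTCAAACAGACGCACATCAGAGTGTTTCAACCTCCTGCAGCTCACTGCCAT
344	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAACTTCACCAACCTCCTGCAGCTCACTGCCAT
278	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
279	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
284	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
288	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
290	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
291	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
293	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
296	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
297	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
299	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
310	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
320	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
339	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
340	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
346	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
349	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
350	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
270	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
270	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCACATCAGAGTGTTTCTTCACCAACCTCCTGCAGCTCACTGCCAT
281	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
281	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
282	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
282	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCTTCACCAACCTCCTGCAGCTCACTGCCAT
323	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
323	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCTTACATGCAGCTCACTGCCAT
348	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
348	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAGGGGAAACGCACTTCACCAACCTCCTGCAGCTCACTGCCAT
273	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
273	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAACCTTCACCAACCTCCTGCAGCTCACTGCCAT
312	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
312	GGAGTTCAAACAGACGCACATCAGAGTGTTTCCCCGAGAAGCCTTCACCAACCTCCTGCAGCTCACTGCCAT
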