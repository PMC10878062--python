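sample_id	sampling_month	maturity	genotype	mutation
269	8	Immature	-/-	del 1/del 1
271	8	Immature	-/-	del 8/del 8
280	8	Immature	-/-	del 1/del 1
283	8	Immature	-/-	del 17/del 17
287	8	Immature	-/-	ins 17/ins 17
292	8	Immature	-/-	ins 8/ins 8
294	8	Immature	-/-	del 17/del 17
317	12	Immature	-/-	del 17/del 14
322	12	Immature	-/-	del 1/ins 8
324	12	Immature	-/-	4I4M3I
342	12	Immature	-/-	del 17/del 17
344	12	Immature	-/-	del 1/del 1
278	8	Immature	if/if	del 3/del 3
279	8	Mature	if/if	del 3/del 3
284	8	Mature	if/if	del 3/del 3
288	8	Immature	if/if	del 3/del 3
290	8	Immature	if/if	del 3/del 3
291	8	Immature	if/if	del 3/del 3
293	8	Immature	if/if	del 3/del 3
296	8	Immature	if/if	del 3/del 3
297	8	Immature	if/if	del 3/del 3
299	8	Mature	if/if	del 3/del 3
310	12	Immature	if/if	del 3/del 3
320	12	Mature	if/if	del 3/del 3
339	12	Immature	if/if	del 3/del 3
340	12	Mature	if/if	del 3/del 3
346	12	Immature	if/if	del 3/del 3
349	12	Mature	if/if	del 3/del 3
350	12	Immature	if/if	del 3/del 3
270	8	Mature	if/fs	del 3/ins 7
281	8	Mature	if/fs	del 3/del 1
282	8	Immature	if/fs	del 3/del 8
323	12	Mature	if/fs	del 3/del 17
348	12	Mature	if/fs	del 3/ins 8
273	8	Mature	if/wt	del 3/wt
312	12	Mature	if/wt	del 3/wt
272	8	Immature	+/+
341	12	Mature	+/+
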