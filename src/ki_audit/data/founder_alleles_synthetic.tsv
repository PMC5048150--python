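mouse_id	allele_index	state	mosaic
236	1	indel	false
236	2	wild_type	false
237	1	indel	false
237	2	wild_type	false
238	1	indel	false
238	2	wild_type	false
239	1	indel	false
239	2	wild_type	false
240	1	indel	false
240	2	wild_type	false
241	1	indel	false
241	2	wild_type	false
242	1	indel	false
242	2	indel	false
243	1	indel	false
243	2	indel	false
244	1	indel	false
244	2	indel	false
245	1	ki	true
245	2	indel	false
246	1	indel	false
246	2	indel	false
247	1	indel	false
247	2	indel	false
248	1	indel	false
248	2	indel	false
249	1	indel	false
249	2	indel	false
250	1	indel	false
250	2	indel	false
251	1	indel	false
251	2	indel	false
252	1	indel	false
252	2	indel	false
253	1	indel	false
253	2	indel	false
254	1	indel	false
254	2	indel	false
255	1	indel	false
255	2	indel	false
256	1	indel	false
256	2	indel	false
257	1	indel	false
257	2	indel	false
258	1	indel	false
258	2	indel	false
259	1	ki	true
259	2	indel	false
260	1	indel	false
260	2	indel	false
261	1	indel	false
261	2	indel	false
262	1	indel	false
262	2	indel	false
263	1	indel	false
263	2	indel	false
264	1	indel	false
264	2	indel	false
265	1	indel	false
265	2	indel	false
266	1	indel	false
266	2	indel	false
267	1	indel	false
267	2	indel	false
268	1	ki	false
268	2	indel	false
269	1	indel	false
269	2	indel	false
270	1	indel	false
270	2	indel	false
271	1	indel	false
271	2	indel	false
272	1	indel	false
272	2	indel	false
273	1	indel	false
273	2	indel	false
274	1	indel	false
274	2	indel	false
275	1	indel	false
275	2	indel	false
276	1	indel	false
276	2	indel	false
277	1	indel	false
277	2	indel	false
278	1	indel	false
278	2	indel	false
279	1	indel	false
279	2	indel	false
280	1	indel	false
280	2	indel	false
281	1	indel	false
281	2	indel	false
282	1	indel	false
282	2	indel	false
283	1	ki	false
283	2	indel	false
284	1	indel	false
284	2	indel	false
285	1	indel	false
285	2	indel	false
286	1	indel	false
286	2	indel	false
287	1	indel	false
287	2	indel	false
288	1	indel	false
288	2	indel	false
289	1	indel	false
289	2	indel	false
290	1	indel	false
290	2	indel	false
291	1	indel	false
291	2	indel	false
292	1	indel	false
292	2	indel	false
293	1	indel	false
293	2	indel	false
294	1	indel	false
294	2	indel	false
295	1	indel	false
295	2	indel	false
296	1	indel	false
296	2	indel	false
297	1	indel	false
297	2	indel	false
298	1	indel	false
298	2	indel	false
299	1	indel	false
299	2	indel	false
300	1	indel	false
300	2	indel	false
301	1	indel	false
301	2	indel	false
302	1	indel	false
302	2	indel	false
303	1	indel	false
303	2	indel	false
304	1	indel	false
304	2	indel	false
305	1	indel	false
305	2	indel	false
306	1	ki	false
306	2	indel	false
307	1	indel	false
307	2	indel	false
308	1	indel	false
308	2	indel	false
309	1	indel	false
309	2	indel	false
310	1	indel	false
310	2	indel	false
311	1	indel	false
311	2	indel	false
312	1	indel	false
312	2	indel	false
313	1	indel	false
313	2	indel	false
314	1	indel	false
314	2	indel	false
315	1	indel	false
315	2	indel	false
316	1	ki	false
316	2	indel	false
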