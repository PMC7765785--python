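replicate	lcc_size
0	5
1	3
2	4
3	4
4	4
5	3
6	2
7	4
8	3
9	2
10	2
11	5
12	3
13	2
14	2
15	3
16	2
17	3
18	3
19	3
20	3
21	5
22	6
23	5
24	4
25	3
26	3
27	3
28	3
29	4
30	4
31	2
32	2
33	4
34	3
35	2
36	2
37	2
38	3
39	2
40	3
41	3
42	3
43	2
44	4
45	4
46	3
47	4
48	2
49	4
50	2
51	4
52	4
53	3
54	2
55	3
56	2
57	4
58	2
59	3
60	3
61	2
62	3
63	2
64	2
65	5
66	2
67	2
68	4
69	4
70	2
71	3
72	2
73	2
74	4
75	2
76	2
77	2
78	2
79	4
80	4
81	4
82	2
83	3
84	4
85	3
86	4
87	3
88	3
89	3
90	3
91	4
92	3
93	4
94	5
95	5
96	2
97	3
98	2
99	3
100	3
101	2
102	5
103	3
104	2
105	3
106	2
107	3
108	4
109	4
110	5
111	3
112	5
113	4
114	3
115	2
116	3
117	4
118	4
119	5
120	2
121	0
122	4
123	2
124	2
125	4
126	2
127	4
128	6
129	2
130	3
131	4
132	2
133	4
134	2
135	5
136	3
137	5
138	3
139	2
140	2
141	3
142	5
143	5
144	2
145	4
146	4
147	2
148	4
149	2
150	5
151	2
152	5
153	2
154	3
155	3
156	4
157	2
158	2
159	4
160	3
161	4
162	3
163	2
164	4
165	2
166	3
167	2
168	4
169	2
170	3
171	3
172	0
173	3
174	3
175	3
176	4
177	2
178	3
179	3
180	4
181	2
182	3
183	2
184	4
185	4
186	3
187	2
188	3
189	3
190	2
191	4
192	4
193	3
194	4
195	3
196	2
197	3
198	5
199	2
200	4
201	5
202	2
203	2
204	3
205	4
206	3
207	4
208	3
209	5
210	2
211	3
212	6
213	4
214	2
215	2
216	0
217	2
218	5
219	4
220	2
221	4
222	2
223	4
224	5
225	2
226	4
227	4
228	2
229	2
230	2
231	5
232	3
233	2
234	4
235	2
236	4
237	2
238	2
239	3
240	3
241	3
242	2
243	2
244	3
245	3
246	4
247	3
248	2
249	4
250	3
251	3
252	2
253	3
254	3
255	2
256	3
257	2
258	2
259	3
260	3
261	2
262	4
263	4
264	4
265	2
266	4
267	2
268	4
269	5
270	2
271	4
272	4
273	3
274	2
275	3
276	4
277	2
278	4
279	3
280	4
281	4
282	5
283	2
284	6
285	2
286	2
287	2
288	3
289	6
290	3
291	3
292	2
293	2
294	4
295	3
296	5
297	2
298	2
299	3
300	4
301	3
302	3
303	3
304	4
305	3
306	4
307	3
308	2
309	4
310	4
311	4
312	3
313	2
314	2
315	2
316	0
317	2
318	3
319	3
320	4
321	3
322	6
323	3
324	3
325	4
326	3
327	5
328	4
329	2
330	2
331	2
332	2
333	3
334	3
335	2
336	2
337	4
338	4
339	2
340	2
341	2
342	3
343	3
344	3
345	2
346	2
347	3
348	2
349	3
350	2
351	2
352	4
353	4
354	2
355	4
356	3
357	6
358	2
359	2
360	5
361	2
362	3
363	2
364	5
365	4
366	2
367	4
368	7
369	2
370	3
371	2
372	2
373	2
374	2
375	3
376	2
377	5
378	3
379	3
380	4
381	2
382	3
383	4
384	3
385	2
386	4
387	3
388	3
389	2
390	2
391	2
392	2
393	4
394	3
395	4
396	3
397	3
398	2
399	3
400	3
401	3
402	2
403	3
404	3
405	4
406	2
407	2
408	2
409	2
410	5
411	4
412	3
413	5
414	3
415	3
416	2
417	4
418	7
419	3
420	5
421	3
422	3
423	2
424	3
425	3
426	2
427	0
428	2
429	3
430	3
431	4
432	3
433	5
434	6
435	3
436	3
437	2
438	2
439	2
440	2
441	4
442	3
443	2
444	3
445	2
446	3
447	3
448	2
449	3
450	5
451	3
452	2
453	2
454	2
455	4
456	2
457	2
458	2
459	5
460	4
461	2
462	2
463	2
464	4
465	6
466	3
467	4
468	4
469	2
470	3
471	2
472	4
473	2
474	4
475	2
476	4
477	3
478	2
479	3
480	5
481	2
482	3
483	2
484	2
485	3
486	3
487	2
488	4
489	2
490	2
491	3
492	2
493	3
494	3
495	2
496	2
497	2
498	3
499	4
500	2
501	5
502	3
503	2
504	3
505	3
506	3
507	2
508	3
509	3
510	3
511	2
512	3
513	2
514	4
515	3
516	4
517	2
518	5
519	2
520	2
521	3
522	2
523	2
524	3
525	2
526	6
527	3
528	3
529	3
530	2
531	3
532	3
533	3
534	2
535	6
536	3
537	3
538	2
539	2
540	3
541	4
542	2
543	4
544	5
545	3
546	2
547	2
548	2
549	2
550	3
551	2
552	2
553	2
554	2
555	3
556	2
557	3
558	3
559	3
560	4
561	2
562	4
563	6
564	2
565	5
566	3
567	2
568	4
569	3
570	2
571	2
572	2
573	4
574	6
575	4
576	2
577	2
578	3
579	6
580	3
581	3
582	5
583	4
584	4
585	4
586	2
587	3
588	2
589	2
590	3
591	3
592	3
593	3
594	2
595	4
596	4
597	3
598	4
599	3
600	4
601	2
602	3
603	3
604	2
605	4
606	3
607	2
608	3
609	3
610	5
611	2
612	4
613	3
614	4
615	3
616	2
617	2
618	3
619	3
620	2
621	3
622	4
623	6
624	4
625	3
626	3
627	2
628	4
629	4
630	2
631	3
632	3
633	2
634	3
635	3
636	4
637	4
638	4
639	4
640	3
641	3
642	4
643	3
644	4
645	3
646	3
647	3
648	3
649	4
650	4
651	2
652	3
653	3
654	4
655	3
656	4
657	3
658	4
659	3
660	2
661	2
662	2
663	4
664	4
665	2
666	5
667	3
668	0
669	3
670	4
671	3
672	4
673	3
674	4
675	4
676	2
677	2
678	3
679	2
680	3
681	4
682	3
683	4
684	2
685	4
686	3
687	2
688	2
689	2
690	3
691	5
692	2
693	2
694	4
695	4
696	2
697	2
698	4
699	3
700	3
701	4
702	4
703	2
704	2
705	5
706	3
707	2
708	2
709	3
710	5
711	5
712	3
713	5
714	2
715	4
716	4
717	3
718	4
719	4
720	4
721	3
722	2
723	2
724	2
725	2
726	2
727	3
728	3
729	2
730	3
731	4
732	3
733	3
734	2
735	3
736	2
737	3
738	3
739	4
740	2
741	2
742	3
743	3
744	2
745	2
746	2
747	4
748	2
749	2
750	3
751	2
752	8
753	4
754	3
755	3
756	2
757	2
758	3
759	4
760	3
761	3
762	4
763	2
764	4
765	3
766	2
767	3
768	2
769	2
770	2
771	4
772	3
773	2
774	3
775	2
776	5
777	3
778	3
779	4
780	2
781	2
782	3
783	4
784	4
785	3
786	6
787	4
788	2
789	2
790	4
791	4
792	2
793	4
794	3
795	2
796	2
797	2
798	2
799	3
800	2
801	2
802	3
803	5
804	3
805	4
806	3
807	5
808	3
809	3
810	3
811	3
812	2
813	2
814	2
815	3
816	3
817	2
818	3
819	3
820	4
821	2
822	3
823	3
824	5
825	2
826	6
827	3
828	3
829	2
830	4
831	2
832	3
833	3
834	3
835	3
836	2
837	2
838	5
839	3
840	4
841	3
842	4
843	2
844	6
845	2
846	2
847	2
848	3
849	2
850	3
851	2
852	3
853	3
854	0
855	2
856	2
857	3
858	2
859	4
860	3
861	4
862	5
863	2
864	3
865	2
866	2
867	5
868	2
869	5
870	4
871	4
872	5
873	4
874	2
875	6
876	3
877	3
878	3
879	5
880	3
881	4
882	3
883	2
884	2
885	4
886	2
887	2
888	4
889	3
890	3
891	0
892	4
893	3
894	3
895	4
896	3
897	2
898	3
899	3
900	3
901	2
902	2
903	4
904	3
905	3
906	2
907	3
908	3
909	5
910	3
911	2
912	2
913	2
914	5
915	6
916	2
917	3
918	4
919	6
920	2
921	3
922	2
923	3
924	3
925	4
926	2
927	7
928	3
929	2
930	2
931	2
932	6
933	4
934	3
935	3
936	5
937	3
938	4
939	4
940	5
941	2
942	2
943	2
944	2
945	2
946	2
947	2
948	4
949	4
950	4
951	5
952	3
953	5
954	3
955	2
956	2
957	4
958	3
959	3
960	2
961	2
962	2
963	3
964	5
965	2
966	4
967	6
968	3
969	5
970	3
971	3
972	2
973	2
974	5
975	2
976	4
977	3
978	5
979	3
980	4
981	4
982	2
983	3
984	3
985	3
986	3
987	4
988	2
989	5
990	4
991	2
992	3
993	3
994	5
995	3
996	2
997	2
998	2
999	3
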