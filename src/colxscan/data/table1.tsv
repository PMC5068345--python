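site	lys_chain	lys_uniprot	lys_helical	arg_chain	arg_uniprot	arg_helical	dogdic_dh	glucosepane_dh
D1	α1b	226	59	α1a	229	62	+85.78	
D2	α2	183	87	α1b	257	90	+109.66	-13.57
D3	α1b	419	252	α2	348	252	+50.08	+38.54
D4	α2	386	290	α1a	458	291	-8.68	+7.88
D5	α1b	494	327	α2	419	323	+20.21	+39.18
D6	α1a	509	342	α2	438	342	+25.38	+4.36
D7	α1a	527	360	α2	456	360	+11.61	-2.30
D8	α2	516	420	α1a	587	420	+72.09	+43.33
D9	α2	549	453	α1a	620	453	+55.07	+76.64
D10	α1b	646	479	α2	579	483	+58.68	+4.08
D11	α1b	731	564	α1a	734	567	-14.33	+23.16
D12	α1a	740	573	α2	669	573	+1.03	+19.28
D13	α1a	748	581	α2	677	581	+9.03	-23.97
D14	α1b	770	603	α2	699	603	+30.74	+73.65
D15	α1b	851	684	α1a	854	687	+83.03	+92.73
D16	α1a	896	729	α2	825	729	+23.38	+55.40
D17	α1a	958	791	α1b	956	789	+53.69	-2.32
D18	α1a	958	791	α2	884	788	-20.38	+65.52
D19	α1b	1022	855	α1a	1025	858	-61.58	+16.13
D20	α2	980	884	α1a	1055	888	-4.85	-34.50
D21	α1a	1085	918	α1b	1082	915	-1.62	+21.91
D22	α2	1020	924	α1a	1094	927	+28.15	-36.13
D23	α2	1029	933	α1a	1100	933	+3.63	
D24	α1a	1141	974	α2	1073	977	+32.15	+90.85
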