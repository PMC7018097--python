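offset	phase
-73	minor_in
-72	minor_in
-71	minor_in
-70	unassigned
-69	unassigned
-68	minor_out
-67	minor_out
-66	minor_out
-65	unassigned
-64	unassigned
-63	minor_in
-62	minor_in
-61	minor_in
-60	unassigned
-59	unassigned
-58	minor_out
-57	minor_out
-56	minor_out
-55	minor_out
-54	unassigned
-53	minor_in
-52	minor_in
-51	minor_in
-50	minor_in
-49	unassigned
-48	minor_out
-47	minor_out
-46	minor_out
-45	minor_out
-44	unassigned
-43	unassigned
-42	minor_in
-41	minor_in
-40	minor_in
-39	unassigned
-38	unassigned
-37	minor_out
-36	minor_out
-35	minor_out
-34	unassigned
-33	unassigned
-32	minor_in
-31	minor_in
-30	minor_in
-29	unassigned
-28	unassigned
-27	minor_out
-26	minor_out
-25	minor_out
-24	unassigned
-23	unassigned
-22	minor_in
-21	minor_in
-20	minor_in
-19	minor_in
-18	unassigned
-17	minor_out
-16	minor_out
-15	minor_out
-14	minor_out
-13	unassigned
-12	minor_in
-11	minor_in
-10	minor_in
-9	minor_in
-8	unassigned
-7	unassigned
-6	minor_out
-5	minor_out
-4	minor_out
-3	unassigned
-2	unassigned
-1	minor_in
0	minor_in
1	minor_in
2	unassigned
3	unassigned
4	minor_out
5	minor_out
6	minor_out
7	unassigned
8	unassigned
9	minor_in
10	minor_in
11	minor_in
12	minor_in
13	unassigned
14	minor_out
15	minor_out
16	minor_out
17	minor_out
18	unassigned
19	minor_in
20	minor_in
21	minor_in
22	minor_in
23	unassigned
24	unassigned
25	minor_out
26	minor_out
27	minor_out
28	unassigned
29	unassigned
30	minor_in
31	minor_in
32	minor_in
33	unassigned
34	unassigned
35	minor_out
36	minor_out
37	minor_out
38	unassigned
39	unassigned
40	minor_in
41	minor_in
42	minor_in
43	unassigned
44	unassigned
45	minor_out
46	minor_out
47	minor_out
48	minor_out
49	unassigned
50	minor_in
51	minor_in
52	minor_in
53	minor_in
54	unassigned
55	minor_out
56	minor_out
57	minor_out
58	minor_out
59	unassigned
60	unassigned
61	minor_in
62	minor_in
63	minor_in
64	unassigned
65	unassigned
66	minor_out
67	minor_out
68	minor_out
69	unassigned
70	unassigned
71	minor_in
72	minor_in
73	minor_in
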