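PK	C.art	C.alb	C.clu	S.fon	S.sal	O.tsh
01.1	Cart23	Calb16	Cclu28	Sf25	Ssa20b	Ots13q
01.2	Cart14	Calb33	Cclu35	Sf38	Ssa09c	Ots14q
02.1	Cart01a	Calb02b^*	Cclu04a	Sf06a	Ssa26	Ots04q
02.2	Cart12	Calb02b^*	Cclu04a^*	Sf28	Ssa11a	Ots12q
03.1	Cart25	Calb19	Cclu25	Sf22	Ssa14a	Ots10q
03.2	Cart26	Calb22	Cclu26	Sf11	Ssa03a	Ots28
04.1	Cart30	Calb29	Cclu16	Sf33	Ssa09b	Ots08q
04.2	Cart21	Calb30	Cclu29	Sf07b	Ssa05a	Ots21
05.1	Cart06b	Calb01a	Cclu05a	Sf01a	Ssa19b	Ots24
05.2	Cart18	Calb35 or Calb40	Cclu15	Sf27	Ssa28	Ots25
06.1	Cart06a	Calb01b	Cclu05b	Sf01b	Ssa01b	Ots01q
06.2	Cart15	Calb27	Cclu05b^*	Sf36	Ssa18a	Ots06q
07.1	Cart20	Calb06	Cclu13	Sf08b	Ssa13b	Ots09p
07.2	Cart19	Calb07	Cclu08	Sf09	Ssa04b	Ots30
08.1	Cart27	Calb17	Cclu36	Sf04a	Ssa23	Ots01p
08.2	Cart03a	Calb08	Cclu06a	Sf17	Ssa10a	Ots05q
09.1	Cart03b*	not identified	Cclu06b	Sf42	Ssa02b	Ots32
09.2	Cart34*	not identified	not identified	Sf03b	Ssa12a	Ots02q
10.1	Cart08a	Calb20b	Cclu10	Sf23	Ssa27	Ots13p
10.2	Cart04b	Calb09a	Cclu24a	Sf34	Ssa14b	Ots31
11.1	Cart05a	Calb13b	Cclu18	Sf14	Ssa06a	Ots27
11.2	Cart09	Calb34	not identified	Sf08a	Ssa03b	Ots09q
12.1	Cart33	Calb14	Cclu27	Sf18	Ssa13a	Ots22
12.2	Cart16	Calb28	Cclu14	Sf30	Ssa15b	Ots16q
13.1	Cart17	Calb25	Cclu34	Sf06b	Ssa24	Ots04p
13.2	Cart32	Calb31	Cclu37	Sf40	Ssa20a	Ots12p
14.1	Cart01b	Calb02a	Cclu04b	Sf13	Ssa01c	Ots20
14.2	Cart38	Calb11	Cclu33	Sf10	Ssa11b	Ots33
15.1	Cart10	Calb18	Cclu31	Sf35	Ssa09a	Ots08p
15.2	Cart31	Calb10	Cclu22	Sf12	Ssa01a	Ots11q
16.1	Cart07a	Calb03b	Cclu02b or Cclu03	Sf26	Ssa21	Ots26
16.2	Cart28	Calb21	Cclu32	Sf24	Ssa25	Ots03q
17.1	Cart24	Calb05	Cclu38	Sf03a	Ssa12b	Ots02p
17.2	Cart22	Calb12	Cclu21	Sf21	Ssa22	Ots07q
18.1	Cart29	Calb24	Cclu40	Sf19	Ssa15a	Ots05p
18.2	Cart37	Calb23	Cclu17	Sf31	Ssa06b	Ots18
19.1	Cart13	Calb04	Cclu30	Sf15	Ssa10b	Ots19
19.2	Cart11	Calb15b	Cclu11	Sf20	Ssa16a	Ots06p
20.1	Cart08b^	Calb36	Cclu01a	Sf07a	Ssa05b	Ots23
20.2	Cart02b	Calb20a	not identified	Sf29	Ssa02a	Ots03p
21.1	Cart05b	Calb13a	Cclu12	Sf05b	Ssa29	Ots29
21.2	Cart36	Calb26	Cclu39	Sf16	Ssa19a	Ots16p
22.1	Cart02a	Calb39^	not identified	Sf39	Ssa17a	Ots07p
22.2	not identified	Calb15a	Cclu19^	Sf05a	Ssa16b	Ots14p
23.1	Cart07b^*	Calb03a	Cclu02a	Sf02b	Ssa07b	Ots15p
23.2	Cart07b^*	missing	Cclu01b^	Sf37	Ssa17b	Ots17
24.1	Cart04a	Calb09b	Cclu24b	Sf02a	Ssa07a	Ots15q
24.2	Cart35	Calb32	Cclu23	Sf32	Ssa18b	Ots10p
25.1	not identified	not identified	Cclu09^	Sf04b	Ssa04a	Ots34
25.2	not identified	not identified	not identified	Sf41	Ssa08a	Ots11p
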