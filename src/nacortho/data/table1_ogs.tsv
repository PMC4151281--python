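og_id	species	member_id	pseudogene
1a	Vv	VvNAC56	0
1a	At	ANAC074	0
1a	Os	Os02g41450.1	0
1a	Os	Os02g56600.1	0
1a	Os	Os03g01870.1	0
1a	Os	Os04g43560.1	0
1a	Os	Os10g33760.1	0
1a	Ma	Achr1T10860	0
1a	Ma	Achr1T20530	0
1a	Ma	Achr5T18670	0
1a	Ma	Achr6T36550	0
1a	Ma	Achr8T18980	0
1a	Ma	Achr11T00880	0
1a	Ma	Achr11T22760	0
1a	Ma	AchrUn_randomT17260	0
1a	Ma	AchrUn_randomT02760	0
1b	Vv	VvNAC33	0
1b	At	ANAC021/022	0
1b	At	ANAC_At3g12977.1	0
1b	Os	Os02g06950.1	0
1b	Os	Os04g52810.1	0
1b	Os	Os06g46270.1	0
1b	Os	Os08g10080.1	0
1b	Os	Os12g41680.1	0
1b	Ma	Achr3T23360	0
1b	Ma	Achr5T00500	0
1b	Ma	Achr5T26640	0
1b	Ma	Achr6T30050	0
1b	Ma	Achr6T31350	0
1b	Ma	Achr8T07120	0
1b	Ma	Achr8T33310	0
1b	Ma	Achr9T10210	0
1b	Ma	Achr9T26140	0
1b	Ma	Achr11T25720	0
1c	Vv	VvNAC65	0
1c	At	ANAC038/039	0
1c	Os	Os09g32260.1	0
1c	Ma	Achr6T01770	0
1c	Ma	Achr7T19680	0
1c	Ma	Achr8T24680	0
1d	Vv	VvNAC16	0
1d	At	ANAC054	0
1d	At	ANAC098	0
1d	Os	Os06g23650.1	0
1d	Ma	Achr10T22350	0
1d	Ma	Achr10T26180	0
1e	Vv	VvNAC14	0
1e	At	ANAC031	0
1e	Os	Os08g40030.1	0
1e	Ma	Achr9T20090	0
1f	Vv	VvNAC06	0
1f	At	ANAC058	0
1f	Os	Os03g42630.1	0
1f	Ma	Achr8T18420	0
1f	Ma	Achr9T00570	1
1f	Ma	Achr10T19900	0
1g	Vv	VvNAC61	0
1g	At	ANAC046	0
1g	At	ANAC087	0
1g	Os	Os01g01470.1	0
1g	Os	Os01g29840.1	0
1g	Os	Os03g21030.1	0
1g	Os	Os07g48550.1	0
1g	Os	Os11g03310.1	0
1g	Os	Os11g03370.1	0
1g	Os	Os12g03050.1	0
1g	Ma	Achr3T09520	0
1g	Ma	Achr3T18020	0
1g	Ma	Achr5T07600	0
1g	Ma	Achr6T08600	0
1g	Ma	Achr6T32290	0
1g	Ma	Achr7T18330	0
1g	Ma	Achr8T21470	0
1g	Ma	Achr9T16920	0
1g	Ma	Achr10T05070	0
1h	Vv	VvNAC05	0
1h	Vv	VvNAC11	0
1h	At	ANAC059	0
1h	At	ANAC079/080	0
1h	At	ANAC092	0
1h	At	ANAC100	0
1h	Os	Os02g36880.1	0
1h	Os	Os04g38720.1	0
1h	Ma	Achr6T30570	0
1h	Ma	Achr7T11500	0
1h	Ma	Achr9T27530	0
2a	Vv	VvNAC02	0
2a	Vv	VvNAC22	0
2a	At	ANAC007	0
2a	At	ANAC026	0
2a	At	ANAC101	0
2a	Os	Os02g42970.1	0
2a	Os	Os04g45340.1	0
2a	Os	Os06g01480.1	0
2a	Ma	Achr6T36840	0
2a	Ma	Achr7T06640	0
2a	Ma	Achr8T11590	0
2a	Ma	Achr11T03780	0
2a	Ma	Achr11T17510	0
2b	Vv	VvNAC23	0
2b	At	ANAC037	0
2b	At	ANAC076	0
2b	At	ANAC105	0
2b	Os	Os03g03540.1	0
2b	Os	Os10g38834.1	0
2b	Ma	Achr8T12100	0
2b	Ma	Achr11T03040	0
2c	Vv	VvNAC63	0
2c	At	ANAC030	0
2c	Os	Os04g59470.1	0
2c	Os	Os08g01330.1	0
2c	Ma	Achr3T22360	0
2c	Ma	Achr7T23170	0
2d	Vv	VvNAC70	0
2d	At	ANAC015	0
2d	At	ANAC070	0
2d	Os	Os04g_OsI_35493	0
2d	Ma	Achr2T05640	0
2d	Ma	Achr6T28890	0
2e	Vv	VvNAC68	0
2e	At	ANAC033	0
2e	Os	Os02g15340.1	0
2e	Os	Os06g33940.1	0
2e	Ma	Achr2T20020	0
2e	Ma	Achr10T14400	0
2e	Ma	Achr10T21750	0
2f	Vv	VvNAC24	0
2f	Vv	VvNAC49	0
2f	At	ANAC043	0
2f	At	ANAC066	0
2f	At	ANAC012	0
2f	Os	Os06g04090.1	0
2f	Os	Os08g02300.1	0
2f	Ma	Achr3T12230	0
2f	Ma	Achr7T05980	0
2f	Ma	Achr9T24450	0
2f	Ma	AchrUn_randomT21980	0
3a	Vv	VvNAC08	0
3a	Vv	VvNAC39	0
3a	At	ANAC002	0
3a	At	ANAC032	0
3a	At	ANAC081	0
3a	At	ANAC102	0
3a	Os	Os01g66120.1	0
3a	Os	Os05g34830.1	0
3a	Os	Os11g08210.1	0
3a	Ma	Achr3T18990	0
3a	Ma	Achr6T17720	0
3a	Ma	Achr6T18720	0
3a	Ma	Achr6T25380	0
3a	Ma	Achr7T23250	0
3a	Ma	Achr10T04570	0
3b	Vv	VvNAC44	0
3b	Os	Os01g60020.1	0
3b	Os	Os03g60080.1	0
3b	Os	Os07g12340.1	0
3b	Ma	Achr4T02390	0
3b	Ma	Achr4T10310	0
3b	Ma	Achr5T07590	0
3b	Ma	Achr6T32330	0
3b	Ma	Achr7T21780	0
3b	Ma	Achr10T29200	0
3c	Vv	VvNAC60	0
3c	Vv	VvNAC26	0
3c	At	ANAC047	0
3c	At	ANAC029	0
3c	Os	Os01g01430.1	0
3c	Os	Os03g21060.1	0
3c	Os	Os05g34310.1	0
3c	Os	Os07g48450.1	0
3c	Os	Os11g03300.1	0
3c	Os	Os12g03040.1	0
3c	Ma	Achr3T18010	0
3c	Ma	Achr4T02380	0
3c	Ma	Achr6T32320	0
3c	Ma	Achr7T21770	0
3c	Ma	Achr9T04960	0
3c	Ma	Achr10T12860	0
3c	Ma	AchrUn_randomT17360	0
3d	Vv	VvNAC03	0
3d	Vv	VvNAC43	1
3d	Vv	VvNAC18	0
3d	At	ANAC018	0
3d	At	ANAC025	0
3d	At	ANAC056	0
3d	Os	Os07g37920.1	0
3d	Ma	Achr1T08860	0
3d	Ma	Achr9T19520	0
3e	Vv	VvNAC17	0
3e	At	ANAC072	0
3e	At	ANAC019	0
3e	At	ANAC055	0
4a	Vv	VvNAC64	0
4a	At	ANAC028	0
4a	At	ANAC045	0
4a	At	ANAC086	0
4a	Os	Os03g02800.1	0
4a	Ma	Achr1T02820	0
4a	Ma	Achr8T13430	0
4a	Ma	Achr11T01400	0
4a	Ma	Achr11T16860	0
4a	Ma	AchrUn_randomT08190	0
4b	Vv	VvNAC57	0
4b	At	ANAC057	0
4b	Os	Os09g38000.1	0
4b	Os	Os09g38010.1	0
4b	Ma	Achr3T13880	0
4b	Ma	Achr9T23940	0
4c	Vv	VvNAC13	0
4c	At	ANAC071	0
4c	At	ANAC011	0
4c	At	ANAC096	0
4c	Os	Os10g42130.1	0
4c	Ma	Achr3T18070	0
4c	Ma	Achr5T03360	0
4c	Ma	Achr5T18140	0
4c	Ma	Achr11T17780	0
4d	Vv	VvNAC20	0
4d	Vv	VvNAC21	0
4d	At	ANAC050	0
4d	At	ANAC051/052	0
4d	At	ANAC053	0
4d	At	ANAC077	0
4d	At	ANAC078	0
4d	Os	Os02g57650.1	0
4d	Os	Os08g44820.1	0
4d	Ma	Achr2T04010	0
4d	Ma	Achr9T20400	0
4d	Ma	Achr9T23580	0
4d	Ma	AchrUn_randomT07620	0
4e	Vv	VvNAC48	0
4e	At	ANAC082	0
4e	At	ANAC103	0
4e	Os	Os05g35170.1	0
4e	Os	Os_AK068153	0
4e	Ma	Achr7T23330	0
4e	Ma	Achr10T04530	0
4e	Ma	Achr11T09000	0
4f	Vv	VvNAC69	0
4f	At	ANAC020	0
4g	Vv	VvNAC15	0
4g	At	ANAC013	0
4g	At	ANAC016	0
4g	At	ANAC017	0
4g	Os	Os09g32040.1	0
4g	Ma	Achr8T24280	0
4g	Ma	AchrUn_randomT11980	0
5a	Vv	VvNAC01	0
5a	Vv	VvNAC07	0
5a	Vv	VvNAC73	0
5a	At	ANAC041	0
5a	At	ANAC084	0
5a	At	ANAC097	0
5a	At	ANAC083	0
5a	Os	Os01g70110.1	0
5a	Os	Os08g42400.1	0
5a	Os	Os09g33490.1	0
5a	Os	Os11g31330.1	0
5a	Os	Os12g29330.1	0
5a	Ma	Achr2T21110	0
5a	Ma	Achr3T18680	0
5a	Ma	Achr6T16560	0
5a	Ma	Achr6T20870	0
5a	Ma	Achr6T23840	0
5a	Ma	Achr7T22480	0
5a	Ma	Achr10T16940	0
5a	Ma	Achr10T11910	0
5a	Ma	AchrUn_randomT24680	0
5b	Vv	VvNAC25	0
5b	Vv	VvNAC51	0
5b	Vv	VvNAC52	0
5b	Vv	VvNAC53	0
5b	Vv	VvNAC54	0
5b	Vv	VvNAC55	0
5b	Vv	VvNAC71	0
5b	At	ANAC014	0
5b	At	ANAC062	0
5b	At	ANAC091	0
5b	At	ANAC_At4g35580	0
5b	Os	Os06g01230.1	0
5b	Os	Os08g06140.1	0
5b	Ma	Achr2T11810	0
5b	Ma	Achr3T00330	0
5b	Ma	Achr4T29170	0
5b	Ma	Achr11T07800	0
5b	Ma	AchrUn_randomT04060	0
5c+MS	Vv	VvNAC67	0
5c+MS	At	ANAC040	0
5c+MS	At	ANAC060	0
5c+MS	At	ANAC089	0
5c+MS	Os	Os01g15640.1	0
5c+MS	Ma	Achr5T23620	0
5c+MS	Ma	Achr6T03200	0
6a	Vv	VvNAC40	0
6a	At	ANAC034	0
6a	Os	Os01g66490.1	0
6a	Os	Os05g34600.1	0
6a	Os	Os08g02160.1	0
6a	Ma	Achr7T23650	0
6a	Ma	Achr3T21690	0
6a	Ma	Achr5T17060	0
6a	Ma	Achr10T04320	0
6a	Ma	Achr10T10690	0
6a	Ma	Achr11T08970	0
6a	Ma	Achr11T22590	0
6a	Ma	Achr11T26450	0
6b	Vv	VvNAC10	0
6b	Vv	VvNAC27	0
6b	At	ANAC009	0
6b	At	ANAC094	0
6b	Os	Os08g33910.1	0
6b	Os	Os02g51120.1	0
6b	Ma	Achr6T02680	0
6b	Ma	Achr10T08120	0
6c	Vv	VvNAC28	0
6c	Vv	VvNAC29	0
6c	Vv	VvNAC30	0
6c	Vv	VvNAC31	0
6c	Vv	VvNAC32	0
6c	Vv	VvNAC36	0
6c	At	ANAC_At3g12910.1	0
6c	At	ANAC042	0
6c	Os	Os03g56580.1	0
6c	Os	Os07g04560.1	0
6c	Os	Os12g43530.1	0
6c	Ma	Achr4T23030	0
6c	Ma	Achr4T32010	0
6c	Ma	Achr5T02170	0
6c	Ma	Achr6T31585	0
6c	Ma	Achr7T00860	0
6c	Ma	Achr9T10040	0
6c	Ma	Achr10T08420	0
7a	Vv	VvNAC34	0
7a	Vv	VvNAC37	0
7a	At	ANAC010	0
7a	At	ANAC073	0
7a	Os	Os01g48130.1	0
7a	Os	Os05g48850.1	0
7a	Ma	Achr2T09080	0
7a	Ma	Achr4T02730	0
7a	Ma	Achr6T27000	0
7b	Vv	VvNAC19	0
7b	At	ANAC075	0
7b	At	ANAC099	0
7b	Os	Os01g09550.1	0
7b	Os	Os05g10620.1	0
7b	Os	Os06g36480.1	0
7b	Ma	Achr2T16590	0
7b	Ma	Achr4T30940	0
7b	Ma	Achr6T05480	0
7b	Ma	Achr7T09510	0
7b	Ma	Achr10T27600	0
7c	Vv	VvNAC12	0
7c	At	ANAC008	0
7c	Os	Os06g15690.1	0
7c	Ma	Achr3T07330	0
7c	Ma	Achr6T11230	1
7d	Vv	VvNAC59	0
7d	At	ANAC044	0
7d	At	ANAC085	0
7d	Os	Os04g40140.1	0
7d	Os	Os02g38130.1	0
7d	Ma	Achr9T01880	0
7d	Ma	AchrUn_randomT17050	0
7e	Vv	VvNAC47	0
7e	Vv	VvNAC58	0
7e	At	ANAC104	0
7e	Os	Os02g34970.1	0
7e	Os	Os04g35660.1	0
7e	Ma	Achr6T17670	0
7e	Ma	Achr6T18640	0
7e	Ma	Achr6T25790	0
7e	Ma	Achr10T10790	0
7f	Vv	VvNAC09	0
7f	Os	Os10g21560.1	0
7f	Ma	Achr2T06610	0
7f	Ma	Achr4T07148	0
7f	Ma	Achr7T26050	0
8a	Vv	VvNAC04	0
8a	Vv	VvNAC41	0
8a	At	ANAC036	0
8a	Os	Os03g04070.1	0
8a	Os	Os06g51070.1	0
8a	Ma	Achr1T02710	0
8a	Ma	Achr3T00560	0
8a	Ma	Achr3T14720	0
8a	Ma	Achr5T19060	0
8a	Ma	Achr7T04030	0
8a	Ma	Achr11T01320	0
8a	Ma	AchrUn_randomT08220	0
8b	Vv	VvNAC46	0
8b	Vv	VvNAC62	0
8b	Vv	VvNAC74	0
8b	At	ANAC061	0
8b	At	ANAC090	0
8b	Os	Os01g64310.1	0
8b	Os	Os05g37080.1	0
8b	Os	Os11g05614.1	0
8b	Os	Os11g45950.1	1
8b	Os	Os12g05990.1	0
8b	Ma	Achr6T19400	0
8b	Ma	Achr8T01410	0
8b	Ma	Achr9T29750	0
8b	Ma	Achr10T04720	0
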