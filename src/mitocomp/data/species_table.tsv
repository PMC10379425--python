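# Caridea mitogenomes used in the comparative analysis (GenBank metadata);
# newly_sequenced=1 marks the two Palaemon records this package reproduces.
subfamily	family	species	size_bp	accession	newly_sequenced
Alpheoidea	Alpheidae	Alpheus digitalis	15700	NC_014883	0
Alpheoidea	Alpheidae	Alpheus hoplocheles	15735	NC_038068	0
Alpheoidea	Alpheidae	Alpheus inopinatus	15789	NC_041151	0
Alpheoidea	Alpheidae	Alpheus japonicus	16619	NC_038116	0
Alpheoidea	Alpheidae	Alpheus bellulus	15738	MH796167	0
Alpheoidea	Alpheidae	Alpheus lobidens	15735	KP276147	0
Alpheoidea	Alpheidae	Alpheus randalli	15676	MH796168	0
Alpheoidea	Alpheidae	Synalpheus microneptunus	15603	NC_047307	0
Alpheoidea	Alpheidae	Leptalpheus forceps	15463	MN732884	0
Alpheoidea	Lysmatidae	Lysmata amboinensis	16735	NC_050676	0
Alpheoidea	Lysmatidae	Lysmata boggessi	17345	NC_064049	0
Alpheoidea	Lysmatidae	Lysmata sp.	16758	MW836830	0
Alpheoidea	Lysmatidae	Lysmata debelius	16757	NC_060421	0
Alpheoidea	Lysmatidae	Lysmata vittata	22003	NC_049878	0
Alpheoidea	Lysmatidae	Exhippolysmata ensirostris	16350	MK681888	0
Alpheoidea	Thoridae	Thor amboinensis	15553	NC_051930	0
Alpheoidea	Thoridae	Lebbeus groenlandicus	17399	NC_045223	0
Alpheoidea	Hippolytidae	Saron marmoratus	16330	NC_050677	0
Atyoidea	Atyidae	Stygiocaris lancifera	15787	NC_035404	0
Atyoidea	Atyidae	Stygiocaris stylifera	15812	NC_035411	0
Atyoidea	Atyidae	Typhlatya arfeae	15887	NC_035410	0
Atyoidea	Atyidae	Typhlatya consobrina	15758	NC_035407	0
Atyoidea	Atyidae	Typhlatya dzilamensis	15892	NC_035408	0
Atyoidea	Atyidae	Typhlatya galapagensis	16430	NC_035402	0
Atyoidea	Atyidae	Typhlatya garciai	15318	NC_035409	0
Atyoidea	Atyidae	Typhlatya iliffei	15926	NC_035401	0
Atyoidea	Atyidae	Typhlatya miravetensis	15865	NC_036335	0
Atyoidea	Atyidae	Typhlatya mitchelli	15814	NC_035403	0
Atyoidea	Atyidae	Typhlatya monae	16007	NC_035405	0
Atyoidea	Atyidae	Typhlatya pearsei	15798	NC_035400	0
Atyoidea	Atyidae	Typhlatya taina	15790	NC_035399	0
Atyoidea	Atyidae	Typhlopatsa pauliani	15824	NC_035406	0
Atyoidea	Atyidae	Typhlatya sp.	15870	KX844713	0
Atyoidea	Atyidae	Caridina gracilipes	15550	NC_024751	0
Atyoidea	Atyidae	Caridina indistincta	15461	NC_039593	0
Atyoidea	Atyidae	Caridina longshan	15556	OP177695	0
Atyoidea	Atyidae	Caridina multidentata	15825	NC_038067	0
Atyoidea	Atyidae	Caridina nilotica	15497	NC_030219	0
Atyoidea	Atyidae	Neocaridina davidi	15564	MN418055	0
Atyoidea	Atyidae	Paratya australiensis	15990	NC_027603	0
Atyoidea	Atyidae	Halocaridina rubra	16065	NC_008413	0
Atyoidea	Atyidae	Halocaridinides fowleri	15977	NC_035412	0
Atyoidea	Atyidae	Atyopsis moluccensis	15933	NC_070241	0
Atyoidea	Atyidae	Neocaridina denticulata	15561	NC_023823	0
Palaemonoidea	Palaemonidae	Palaemon adspersus	15736	NC_050168	0
Palaemonoidea	Palaemonidae	Palaemon annandalei	15718	NC_038117	0
Palaemonoidea	Palaemonidae	Palaemon capensis	15925	NC_039373	0
Palaemonoidea	Palaemonidae	Palaemon gravieri	15740	NC_029240	0
Palaemonoidea	Palaemonidae	Palaemon serratus	15758	NC_050266	0
Palaemonoidea	Palaemonidae	Palaemon serenus	15967	NC_027601	0
Palaemonoidea	Palaemonidae	Palaemon varians	14889	MT340090	0
Palaemonoidea	Palaemonidae	Palaemon elegans	15650	MT340089	0
Palaemonoidea	Palaemonidae	Palaemon modestus	15736	MF687349	0
Palaemonoidea	Palaemonidae	Palaemon sinensis	15736	MN372141	0
Palaemonoidea	Palaemonidae	Palaemon tenuidactylus	15735	OP650931	1
Palaemonoidea	Palaemonidae	Palaemon macrodactylus	15744	OQ512152	1
Palaemonoidea	Palaemonidae	Palaemon carinicauda	15730	EF560650	0
Palaemonoidea	Palaemonidae	Macrobrachium nipponense	15806	NC_015073	0
Palaemonoidea	Palaemonidae	Macrobrachium rosenbergii	15772	NC_006880	0
Palaemonoidea	Palaemonidae	Macrobrachium bullatum	15774	KM978918	0
Palaemonoidea	Palaemonidae	Macrobrachium lanchesteri	15694	NC_012217	0
Palaemonoidea	Palaemonidae	Ancylocaris brevicarpalis	16673	NC_061664	0
Palaemonoidea	Palaemonidae	Anchistus australis	15396	NC_046034	0
Palaemonoidea	Palaemonidae	Hymenocera picta	15786	NC_039631	0
Bresilioidea	Alvinocarididae	Alvinocaris chelys	15910	NC_018778	0
Bresilioidea	Alvinocarididae	Alvinocaris longirostris	16022	NC_042497	0
Bresilioidea	Alvinocarididae	Alvinocaris kexueae	15864	MH714459	0
Bresilioidea	Alvinocarididae	Rimicaris paulexa	15909	NC_051948	0
Bresilioidea	Alvinocarididae	Mirocaris indica	15922	NC_054368	0
Bresilioidea	Alvinocarididae	Nautilocaris saintlaurentae	15928	NC_021971	0
Bresilioidea	Alvinocarididae	Opaepele loihi	15905	NC_020311	0
Bresilioidea	Alvinocarididae	Rimicaris exoculata	15902	NC_027116	0
Bresilioidea	Alvinocarididae	Shinkaicaris leurokolos	15903	NC_037487	0
Bresilioidea	Alvinocarididae	Manuscaris liui	15903	MH714461	0
Bresilioidea	Alvinocarididae	Rimicaris kairei	15900	NC_020310	0
Bresilioidea	Alvinocarididae	Rimicaris variabilis	15909	MN419306	0
Pandaloidea	Pandalidae	Bitias brevis	15891	NC_040856	0
Pandaloidea	Pandalidae	Chlorotocus crassicornis	15935	NC_035828	0
Pandaloidea	Pandalidae	Heterocarpus ensifer	15939	NC_040855	0
Pandaloidea	Pandalidae	Pandalus borealis	15956	LC341266	0
Pandaloidea	Pandalidae	Pandalus prensor	17194	MW091549	0
Pandaloidea	Pandalidae	Parapandalus sp.	16037	MH714458	0
Pandaloidea	Pandalidae	Plesionika edwardsii	15956	OP087601	0
Pandaloidea	Pandalidae	Plesionika sindoi	15908	MH714453	0
Pandaloidea	Pandalidae	Plesionika ortmanni	15908	OP650932	0
Pandaloidea	Pandalidae	Plesionika izumiae	16074	OP650933	0
Pandaloidea	Pandalidae	Plesionika lophotes	15933	OP650934	0
Oplophoroidea	Acanthephyridae	Notostomus gibbosus	17590	NC_059935	0
Oplophoroidea	Acanthephyridae	Acanthephyra sp.	16205	MT879756	0
Oplophoroidea	Acanthephyridae	Acanthephyra smithi	17165	MH714455	0
Oplophoroidea	Oplophoridae	Oplophorus spinosus	17346	NC_059714	0
Oplophoroidea	Oplophoridae	Oplophorus typus	16883	MH714457	0
Nematocarcinoidea	Nematocarcinidae	Nematocarcinus gracilis	15919	MH714456	0
Nematocarcinoidea	Rhynchocinetidae	Rhynchocinetes durbanensis	17695	NC_029372	0
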