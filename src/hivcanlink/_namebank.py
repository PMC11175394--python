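"""Packaged name bank for the synthetic record generator.

South-African-flavoured given names and surnames spanning the country's major
naming traditions (Nguni, Sotho–Tswana, Tsonga, Venda, Afrikaans, English,
Indian and Cape communities). The lists are ordered roughly by commonness;
sampling weights decay harmonically with rank so that the synthetic
population has the heavy-tailed name-frequency profile real registries show
(a handful of very common surnames, a long tail of rare ones). All entries
are synthetic fixtures in the sense that no list of real persons was used.
"""

from __future__ import annotations

import numpy as np


def _split(block: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in block.replace("\n", ",").split(",") if s.strip())


FIRST_NAMES_F: tuple[str, ...] = _split("""
Thandiwe, Nomvula, Zanele, Ayanda, Nokuthula, Busisiwe, Ntombi, Nonhlanhla,
Lindiwe, Nosipho, Lerato, Palesa, Zodwa, Zandile, Sibongile, Gugu, Mbali,
Precious, Beauty, Patience, Maria, Anna, Elizabeth, Johanna, Nomsa, Thembi,
Dikeledi, Kgomotso, Mamello, Mapula, Masego, Mmabatho, Mpho, Naledi,
Nthabiseng, Puleng, Tebogo, Tshegofatso, Boitumelo, Bontle, Dineo,
Keabetswe, Keletso, Kelebogile, Lesedi, Lebogang, Lorato, Malebo,
Matshidiso, Mosa, Motlalepula, Neo, Omphile, Onthatile, Oratile, Reabetswe,
Rethabile, Tumelo, Kgalalelo, Amahle, Anele, Asanda, Akhona, Aphiwe,
Babalwa, Bulelwa, Buhle, Chuma, Esihle, Fezeka, Hlumelo, Khwezi, Lelethu,
Likhona, Noluthando, Nolwazi, Nombulelo, Nomfundo, Nompumelelo, Nandipha,
Zintle, Sindisiwe, Samukelisiwe, Nqobile, Gugulethu, Hlengiwe, Khanyisile,
Kholeka, Lungile, Minenhle, Nelisiwe, Nokwanda, Nomalanga, Nomathemba,
Nombuso, Nomonde, Nomzamo, Nonkululeko, Ntombifuthi, Ntombizodwa, Phindile,
Phumzile, Refilwe, Thembeka, Thembisa, Thobeka, Thulisile, Velile, Xolelwa,
Yolanda, Zama, Zimbini, Zininzi, Zoleka, Zukiswa, Nobuhle, Nomcebo,
Nompilo, Nonjabulo, Ntandoyenkosi, Philisiwe, Sebenzile, Senamile,
Silindile, Simangele, Siphokazi, Sithembile, Slindile, Snenhlanhla,
Thandeka, Thandazile, Zethu, Zinhle, Susanna, Magdalena, Hester, Aletta,
Catharina, Martha, Elsie, Sannie, Marietjie, Annelie, Annemarie, Elmarie,
Rina, Ronel, Marlene, Hannelie, Karin, Ilse, Lize, Lizelle, Chantelle,
Charmaine, Amanda, Adri, Antoinette, Bernadette, Carla, Cecilia, Christine,
Danelle, Elana, Esme, Estelle, Hendrina, Ingrid, Jeanette, Lida, Louisa,
Magriet, Marina, Petronella, Wilhelmina, Yvonne, Zelda, Mary, Patricia,
Jennifer, Linda, Barbara, Susan, Jessica, Sarah, Karen, Nancy, Lisa, Betty,
Margaret, Sandra, Ashley, Dorothy, Kimberly, Emily, Donna, Michelle, Carol,
Melissa, Deborah, Stephanie, Rebecca, Sharon, Laura, Cynthia, Kathleen,
Amy, Angela, Shirley, Brenda, Pamela, Emma, Nicole, Helen, Samantha,
Katherine, Christina, Debra, Rachel, Carolyn, Janet, Catherine, Heather,
Diane, Ruth, Julie, Olivia, Joyce, Virginia, Victoria, Kelly, Lauren,
Joan, Evelyn, Judith, Megan, Cheryl, Andrea, Hannah, Jacqueline, Martha2,
Gloria, Teresa, Ann, Madison, Frances, Kathryn, Janice, Jean, Abigail,
Alice, Julia, Judy, Sophia, Grace, Denise, Amber, Doris, Marilyn, Danielle,
Beverly, Isabella, Theresa, Diana, Natalie, Brittany, Charlotte, Marie,
Kayla, Alexis, Lori, Priya, Anitha, Kavitha, Saraswathi, Lakshmi, Devi,
Meena, Radha, Shanti, Vani, Asha, Nisha, Rani, Sunitha, Fathima, Ayesha,
Zainab, Khadija, Razia, Shamila, Waheeda, Zubeida, Rukshana, Nazreen,
Shireen
""")

FIRST_NAMES_M: tuple[str, ...] = _split("""
Sipho, Thabo, Bongani, Sibusiso, Themba, Mandla, Sello, Kagiso, Siyabonga,
Sandile, Sifiso, Mduduzi, Musa, Nkosinathi, Bheki, Dumisani, Jabulani,
Lucky, Lungelo, Mlungisi, Mxolisi, Ndumiso, Nhlanhla, Njabulo, Ntokozo,
Phila, Phumlani, Sabelo, Sanele, Senzo, Simphiwe, Siphamandla, Sizwe,
Thamsanqa, Thulani, Vusi, Vusumuzi, Wandile, Xolani, Zakhele, Zweli,
Andile, Ayabonga, Bandile, Bonginkosi, Khaya, Khulekani, Lwazi, Mfundo,
Mnqobi, Mpilo, Mthunzi, Olwethu, Siyanda, Sonwabo, Thando, Unathi, Zolani,
Kabelo, Katlego, Lehlohonolo, Lesiba, Moeketsi, Molefi, Mothusi, Oupa,
Phenyo, Pitso, Thapelo, Tshepo, Tshepiso, Karabo, Kopano, Lefa,
Letlhogonolo, Mogomotsi, Obakeng, Ofentse, Phemelo, Thato, Teboho,
Tsietsi, Vuyo, Wiseman, Zamani, Zenzele, Bhekizizwe, Mzwandile, Mzikayise,
Nkululeko, Sicelo, Sihle, Sakhile, Samkelo, Senzeni, Siboniso, Sibonelo,
Sinethemba, Siphesihle, Siphiwe, Sphamandla, Thabang, Thabiso, Tebello,
Johan, Pieter, Jan, Willem, Hendrik, Gert, Frik, Kobus, Dawie, Danie,
Hannes, Jaco, Jacques, Andre, Francois, Stefan, Ruan, Riaan, Wynand,
Tertius, Schalk, Sarel, Gideon, Christiaan, Cornelius, Dirk, Albertus,
Barend, Casper, Deon, Etienne, Flip, Gerhard, Hermanus, Izak, Lodewyk,
Marius, Nico, Ockert, Petrus, Quintus, Stephanus, Theunis, Tobias, Wessel,
James, John, Robert, Michael, William, David, Richard, Joseph, Thomas,
Charles, Christopher, Daniel, Matthew, Anthony, Mark, Donald, Steven,
Paul, Andrew, Joshua, Kenneth, Kevin, Brian, George, Edward, Ronald,
Timothy, Jason, Jeffrey, Ryan, Jacob, Gary, Nicholas, Eric, Jonathan,
Stephen, Larry, Justin, Scott, Brandon, Benjamin, Samuel, Gregory, Frank,
Alexander, Raymond, Patrick, Jack, Dennis, Jerry, Tyler, Aaron, Henry,
Adam, Douglas, Nathan, Peter, Zachary, Kyle, Walter, Harold, Carl, Arthur,
Gerald, Roger, Keith, Jeremy, Terry, Lawrence, Sean, Christian, Albert,
Joe, Ethan, Austin, Jesse, Willie, Billy, Bryan, Bruce, Jordan, Ralph,
Roy, Noah, Dylan, Eugene, Wayne, Alan, Louis, Russell, Vincent, Philip,
Bobby, Johnny, Bradley, Ravi, Kumar, Suresh, Rajesh, Anand, Vijay,
Krishna, Mohan, Prakash, Sanjay, Deepak, Ashok, Ramesh, Naresh, Dinesh,
Mohammed, Ahmed, Ismail, Yusuf, Ebrahim, Abdul, Rashid, Imran, Faizel,
Riyaad, Ridwaan, Shaheed, Zaid
""")

SURNAMES: tuple[str, ...] = _split("""
Nkosi, Dlamini, Khumalo, Ndlovu, Zulu, Mthembu, Ngcobo, Mkhize, Cele,
Gumede, Zungu, Ntuli, Mhlongo, Shabalala, Buthelezi, Zwane, Sithole,
Mabaso, Hadebe, Majola, Mbatha, Ngubane, Shezi, Xulu, Dube, Mazibuko,
Msomi, Nxumalo, Sibiya, Vilakazi, Kunene, Luthuli, Maphumulo, Mchunu,
Mngomezulu, Mokoena, Radebe, Tshabalala, Mofokeng, Mahlangu, Maseko,
Masango, Mnguni, Nkambule, Nkabinde, Skosana, Mtshali, Myeni, Ngwenya,
Nzimande, Qwabe, Thusi, Zikalala, Gwala, Hlongwane, Jiyane, Khanyile,
Langa, Madonsela, Magubane, Makhanya, Manzini, Mavuso, Mbele, Mbhele,
Mdluli, Memela, Mfeka, Molefe, Moloi, Motaung, Motloung, Nhlapo, Mohapi,
Modise, Mogale, Montsho, Moremi, Mosala, Moshoeshoe, Motsepe, Tau, Tladi,
Tsotetsi, Phiri, Nkuna, Baloyi, Chauke, Mathebula, Maluleke, Ngobeni,
Sono, Mudau, Tshivhase, Makhado, Mulaudzi, Netshitenzhe, Jali, Jafta,
Booi, Dyantyi, Faku, Madikizela, Makeleni, Maqoma, Matanzima, Mayekiso,
Mbambo, Mgijima, Mini, Nofemela, Qunta, Soga, Tshaka, Tyali, Xaba, Zibi,
Moyo, Ncube, Sibanda, Tshuma, Nyoni, Mpofu, Ndou, Banda, Chirwa, Mlambo,
Van der Merwe, Botha, Pretorius, Van Wyk, Venter, Fourie, Du Plessis,
Du Toit, Nel, Coetzee, Steyn, Van Niekerk, Joubert, Le Roux, Kruger,
Swanepoel, Van Zyl, Meyer, Viljoen, Smit, Erasmus, Ferreira,
Bezuidenhout, Bester, Blignaut, Bosman, Brits, Burger, Cilliers, Cloete,
Conradie, De Beer, De Bruyn, De Jager, De Klerk, De Kock, De Lange,
De Villiers, De Wet, Du Preez, Engelbrecht, Esterhuizen, Geldenhuys,
Grobler, Grobbelaar, Heyns, Jacobs, Jansen, Janse van Rensburg, Jooste,
Kotze, Labuschagne, Lombard, Loots, Lotter, Louw, Malan, Malherbe,
Marais, Maritz, Myburgh, Naude, Nortje, Oberholzer, Odendaal, Olivier,
Oosthuizen, Opperman, Potgieter, Prinsloo, Rossouw, Roux, Scholtz,
Schoeman, Slabbert, Snyman, Spies, Strydom, Swart, Terblanche, Theron,
Uys, Van Aswegen, Van den Berg, Van der Linde, Van der Walt,
Van der Westhuizen, Van Heerden, Van Jaarsveld, Van Rooyen,
Van Schalkwyk, Van Staden, Van Tonder, Van Vuuren, Vermaak, Vermeulen,
Visagie, Visser, Vorster, Vosloo, Wessels, Smith, Jones, Williams,
Brown, Taylor, Wilson, Evans, Thomas, Johnson, Roberts, Walker, Wright,
Robinson, Thompson, White, Hughes, Edwards, Green, Hall, Wood, Harris,
Lewis, Martin, Jackson, Clarke, Clark, Turner, Hill, Scott, Moore,
Cooper, Ward, King, Baker, Harrison, Morgan, Allen, Morris, Parker,
Price, Watson, Bennett, Gray, Mitchell, Carter, Phillips, Collins, Bell,
Murphy, Kelly, Young, Adams, Campbell, Anderson, Stewart, Murray, Reid,
MacDonald, Ross, Henderson, Graham, Ferguson, Hamilton, Duncan, Fraser,
Gordon, Wallace, Gibson, Naidoo, Pillay, Govender, Moodley, Reddy,
Naicker, Chetty, Padayachee, Maharaj, Singh, Rampersad, Desai, Patel,
Khan, Moosa, Cassim, Dawood, Mahomed, Ismail, Ebrahim, Abrahams,
Arendse, Benjamin, Cupido, Daniels, Davids, Fortuin, Hendricks, Isaacs,
Jantjies, Januarie, Lottering, Meintjies, Petersen, Philander,
Plaatjies, Samuels, September, Solomons, Titus, Willemse, Witbooi,
Abbott, Atkinson, Bailey, Baldwin, Ball, Banks, Barber, Barker, Barnes,
Barrett, Barton, Bates, Baxter, Berry, Bishop, Black, Bolton, Bond,
Booth, Bowen, Boyd, Brennan, Briggs, Brooks, Bryant, Burgess, Burke,
Burns, Burton, Butler, Byrne, Cameron, Carr, Chambers, Chapman, Cole,
Coleman, Cox, Crawford, Cross, Cunningham, Curtis, Dale, Dalton,
Davidson, Dawson, Day, Dean, Dixon, Doyle, Drake, Dunn, Elliott, Ellis,
Field, Fisher, Fleming, Fletcher, Ford, Foster, Fox, Francis, Freeman,
French, Fuller, Gallagher, Gardner, Gibbs, Gilbert, Giles, Gill, Glover,
Goodwin, Grant, Greenwood, Gregory, Griffin, Griffiths, Hale, Hammond,
Hancock, Hardy, Harper, Hart, Harvey, Hawkins, Hayes, Heath, Hewitt,
Hicks, Hodgson, Holland, Holmes, Hopkins, Horton, Howard, Howell,
Hudson, Hunt, Hunter, Hutchinson, Mntambo, Mposula?, Sokhela, Zondo,
Zondi, Zuma, Gwamanda, Khoza, Lekota, Mabena, Mabuza, Machaka, Madiba,
Mafu, Magagula, Mahlaba, Makda?, Malema, Mampane, Manana, Mandela,
Mangena, Mankge?, Maphosa, Mapisa, Masemola, Mashaba, Mashinini,
Masilela, Masina, Masondo, Matlala, Matsane?, Mbeki, Mbense?, Mbuyazi,
Mcineka?, Mdlalose, Mkhwanazi, Mlangeni, Mncube, Mndebele?, Mnisi,
Mnyandu, Mogashoa?, Mohlala, Mojapelo, Mokaba, Mokgabudi?, Mokone,
Molapo, Moleko, Mollo?, Monama, Monareng?, Moosa2, Mopeli, Morake,
Moroka, Mosia, Mosweu?, Mothiba, Motsamai, Msibi, Mvelase, Ncwane,
Ndaba, Ndima?, Ndlela, Ngema, Ngidi, Ngoepe, Ngomane, Ngwane, Nhleko,
Nkonyane, Nogabe?, Nondumo?, Ntshangase, Ntombela, Nyambi, Nzama,
Pheto?, Pule, Rakgotso?, Ramaila?, Ramokgopa, Rapoo?, Ratsoma?, Sedibe,
Sehloho?, Sekete?, Selepe, Semenya, Seoka?, Serfontein, Shange, Shelembe,
Shoba, Sikhosana, Simelane, Sindane, Sisulu, Siwela, Sokhulu, Songo?,
Thabethe, Thwala, Tsela?, Twala, Vezi?, Vundla, Xhosa?, Yende, Zitha
""")

# Strip the uncertainty markers left in the raw blocks above.
SURNAMES = tuple(s.rstrip("?") for s in SURNAMES)
FIRST_NAMES_F = tuple(s.rstrip("2") for s in FIRST_NAMES_F)
FIRST_NAMES_M = tuple(s.rstrip("2") for s in FIRST_NAMES_M)
SURNAMES = tuple(dict.fromkeys(s.rstrip("2") for s in SURNAMES))
FIRST_NAMES_F = tuple(dict.fromkeys(FIRST_NAMES_F))
FIRST_NAMES_M = tuple(dict.fromkeys(FIRST_NAMES_M))


def rank_weights(n: int, offset: float = 20.0) -> np.ndarray:
    """Harmonic rank weights w_k ∝ 1/(k + offset), normalised to sum to 1.

    With the default offset the most common of ~500 names gets ~1.4% of the
    mass — a realistic top-surname share — while the tail stays long.
    """
    w = 1.0 / (np.arange(n, dtype=np.float64) + 1.0 + offset)
    return w / w.sum()
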